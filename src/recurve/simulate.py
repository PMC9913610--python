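"""Synthetic pedigrees, Re phenotypes and genotypes with known truth.

The generator mirrors the generative side of the models this package
fits: a multi-generation pedigree with sire reuse (hence non-trivial
inbreeding), animal trajectory effects sampled from ``Ka (x) A`` by
Mendelian-sampling recursion, permanent-environment / HYS / class-wise
residual effects at magnitudes matching the cattle study conditions, and
biallelic genotypes with planted causal loci behind a pseudo-phenotype.
Every dataset is accompanied by a :class:`TruthLedger` so that parameter
recovery can be tested against the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import legendre
from .pedigree import Pedigree, inbreeding_classes, inbreeding_meuwissen_luo, sort_pedigree
from .phenotypes import AFC_OPT_MONTHS, CI_OPT_MONTHS, DAYS_PER_MONTH, N_RES_CLASSES
from .plinkio import GenotypeMatrix

# Trajectory coefficient covariance whose implied genetic variance falls
# from ~117 at the first calving to ~35-41 at later ones with high positive
# correlations along the trajectory (fertility study conditions).
KA_TRAJECTORY = np.array([
    [97.53, -17.48, 6.74],
    [-17.48, 7.47, -2.03],
    [6.74, -2.03, 1.52],
])
# Residual class variances chosen so per-calving totals fall from ~507 to ~95
RESID_CLASSES = (345.0, 110.0, 54.0, 33.0, 22.0, 13.0)

# Repeatability-model generating components
REP_COMPONENTS = {"animal": 91.82, "pe": 105.55, "hys": 27.38, "residual": 79.52}


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic generator."""

    seed: int
    n_founders: int = 80
    n_generations: int = 4
    cows_per_generation: int = 120
    n_sires_per_generation: int = 6      # heavy reuse -> inbreeding builds up
    female_fraction: float = 0.8

    # phenotype model
    mu: float = 72.0
    Ka_true: np.ndarray = field(default_factory=lambda: KA_TRAJECTORY.copy())
    sigma_a2_true: float = REP_COMPONENTS["animal"]      # repeatability variant
    sigma_p2_true: float = 30.0
    sigma_hys2_true: float = 15.0
    sigma_e2_true: tuple = RESID_CLASSES
    cn_effect: tuple = (6.0, -2.0)       # b1 x + b2 x^2 on the standardized scale
    fc_slope: float = -20.0              # Re points per unit inbreeding
    max_cn: int = 9
    retention: float = 0.8               # geometric dropout per extra calving
    n_herds: int = 8
    start_year: int = 1990
    years_between_generations: int = 3
    n_seasons: int = 2

    # genotype block
    n_samples: int = 252
    n_markers: int = 5000
    n_chromosomes: int = 29
    n_causal: int = 5
    causal_h2: float = 0.15
    missing_rate: float = 0.01
    fst: float = 0.0                     # >0 adds 2-subpopulation structure


@dataclass
class TruthLedger:
    """Generating values recorded alongside every simulated dataset."""

    variance_components: dict
    coefficients: pd.DataFrame | None = None     # per-animal true trajectory coefs
    egv: pd.DataFrame | None = None              # per-animal true per-calving values
    breeding_values: pd.Series | None = None     # repeatability variant
    causal_markers: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.Series({k: str(v) for k, v in self.variance_components.items()}).to_csv(
            outdir / "truth_components.csv", header=False)
        if self.coefficients is not None:
            self.coefficients.to_csv(outdir / "truth_coefficients.csv")
        if self.egv is not None:
            self.egv.to_csv(outdir / "truth_egv.csv")
        if self.breeding_values is not None:
            self.breeding_values.to_csv(outdir / "truth_breeding_values.csv", header=False)
        if self.causal_markers is not None:
            self.causal_markers.to_csv(outdir / "truth_causal.csv", index=False)


# ---------------------------------------------------------------------------
# pedigree

def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Overlapping-generation pedigree with random mating and sire reuse."""
    rng = rng or np.random.default_rng(cfg.seed)
    rows = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"A{counter:06d}"

    males, females = [], []
    for _ in range(cfg.n_founders):
        aid = new_id()
        sex = "F" if rng.random() < cfg.female_fraction else "M"
        (females if sex == "F" else males).append(aid)
        rows.append((aid, "0", "0", cfg.start_year, sex))

    for g in range(1, cfg.n_generations + 1):
        year = cfg.start_year + g * cfg.years_between_generations
        sires = list(rng.choice(males, size=min(cfg.n_sires_per_generation, len(males)),
                                replace=False))
        new_f, new_m = [], []
        for _ in range(cfg.cows_per_generation):
            aid = new_id()
            sire = sires[rng.integers(len(sires))]
            dam = females[rng.integers(len(females))]
            sex = "F" if rng.random() < cfg.female_fraction else "M"
            rows.append((aid, sire, dam, year, sex))
            (new_f if sex == "F" else new_m).append(aid)
        females = females + new_f
        males = males + new_m if new_m else males

    frame = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year", "sex"])
    return sort_pedigree(frame)


# ---------------------------------------------------------------------------
# breeding values

def simulate_breeding_values(ped: Pedigree, Ka_true: np.ndarray,
                             rng: np.random.Generator,
                             F: np.ndarray | None = None) -> pd.DataFrame:
    """Trajectory coefficients distributed N(0, Ka (x) A).

    Founders are drawn from N(0, Ka); each offspring is the parent average
    plus a Mendelian-sampling deviation with covariance d_i * Ka where
    d_i = 0.5 - 0.25 (F_sire + F_dam) (0.75 - 0.25 F for one known parent,
    1 for founders).
    """
    Ka_true = np.atleast_2d(np.asarray(Ka_true, dtype=float))
    k = Ka_true.shape[0]
    L = np.linalg.cholesky(Ka_true)
    if F is None:
        F = inbreeding_meuwissen_luo(ped)
    n = len(ped)
    a = np.zeros((n, k))
    z = rng.standard_normal((n, k)) @ L.T
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            a[i] = z[i]
        elif s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
            a[i] = 0.5 * (a[s] + a[d]) + np.sqrt(di) * z[i]
        else:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
            a[i] = 0.5 * a[p] + np.sqrt(di) * z[i]
    return pd.DataFrame(a, index=ped.ids, columns=[f"a{j}" for j in range(k)])


# ---------------------------------------------------------------------------
# records

def simulate_records(ped: Pedigree, bvs: pd.DataFrame, cfg: SimConfig,
                     rng: np.random.Generator,
                     trajectory: bool = True,
                     F: np.ndarray | None = None) -> tuple[pd.DataFrame, TruthLedger]:
    """Analysis-ready Re records for every simulated cow.

    ``trajectory=True`` uses the random-regression generative model
    (coefficients x Legendre basis, class-wise residuals); ``False`` uses
    the repeatability model (constant animal effect, single residual
    class, taking the first coefficient column of ``bvs`` as the breeding
    value).
    """
    if F is None:
        F = inbreeding_meuwissen_luo(ped)
    cows = [i for i in range(len(ped))
            if ped.sex[i] == "F" and ped.birth_year[i] > ped.birth_year.min()]
    herd_of = {i: f"H{rng.integers(cfg.n_herds) + 1}" for i in cows}
    pe = {i: rng.normal(0.0, np.sqrt(cfg.sigma_p2_true)) for i in cows}
    hys_effects: dict[str, float] = {}

    basis = legendre.Basis.on_calvings(bvs.shape[1] - 1) if trajectory else None
    b1, b2 = cfg.cn_effect
    resid = np.asarray(cfg.sigma_e2_true, dtype=float)

    rows = []
    for i in cows:
        n_calvings = 1
        while n_calvings < cfg.max_cn and rng.random() < cfg.retention:
            n_calvings += 1
        aid = ped.ids[i]
        for cn in range(1, n_calvings + 1):
            x = float(legendre.standardize_cn(float(cn)))
            fixed = cfg.mu + b1 * x + b2 * x ** 2 + cfg.fc_slope * F[i]
            if trajectory:
                genetic = float(basis.Phi[cn - 1] @ bvs.loc[aid].to_numpy())
                e_sd = np.sqrt(resid[min(cn, N_RES_CLASSES) - 1])
            else:
                genetic = float(bvs.loc[aid].iloc[0])
                e_sd = np.sqrt(cfg.sigma_e2_true if np.isscalar(cfg.sigma_e2_true)
                               else resid[0])
            year = int(ped.birth_year[i]) + 2 + (cn - 1)
            season = int(rng.integers(cfg.n_seasons)) + 1
            hys = f"{herd_of[i]}_{year}_{season}"
            if hys not in hys_effects:
                hys_effects[hys] = rng.normal(0.0, np.sqrt(cfg.sigma_hys2_true))
            y = fixed + genetic + pe[i] + hys_effects[hys] + rng.normal(0.0, e_sd)
            rows.append({"cow": aid, "cn": cn,
                         "age_months": AFC_OPT_MONTHS + (cn - 1) * CI_OPT_MONTHS,
                         "re": y, "hys": hys,
                         "res_class": min(cn, N_RES_CLASSES),
                         "year": year, "fc": F[i],
                         "fc_class": int(inbreeding_classes(np.array([F[i]]))[0]),
                         "herd": herd_of[i], "season": season})
    table = pd.DataFrame(rows)

    if trajectory:
        egv = pd.DataFrame(legendre.egv_trajectory(bvs.to_numpy(), basis.Phi),
                           index=bvs.index,
                           columns=[f"cn{int(c)}" for c in basis.points])
        ledger = TruthLedger(
            variance_components={"Ka": cfg.Ka_true, "pe": cfg.sigma_p2_true,
                                 "hys": cfg.sigma_hys2_true,
                                 "residual": tuple(resid)},
            coefficients=bvs, egv=egv)
    else:
        ledger = TruthLedger(
            variance_components={"animal": float(np.atleast_2d(cfg.Ka_true)[0, 0])
                                 if cfg.Ka_true is not None else cfg.sigma_a2_true,
                                 "pe": cfg.sigma_p2_true, "hys": cfg.sigma_hys2_true,
                                 "residual": float(resid[0])},
            breeding_values=bvs.iloc[:, 0])
    return table, ledger


def simulate_rep_dataset(cfg: SimConfig) -> tuple[Pedigree, pd.DataFrame, TruthLedger]:
    """Pedigree + records generated under the repeatability model.

    Animal variance comes from ``cfg.sigma_a2_true``; the permanent
    environment, HYS and residual magnitudes default to the repeatability
    study conditions (:data:`REP_COMPONENTS`).
    """
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    F = inbreeding_meuwissen_luo(ped)
    bvs = simulate_breeding_values(ped, [[cfg.sigma_a2_true]], rng, F)
    cfg_rep = SimConfig(**{**cfg.__dict__,
                           "Ka_true": np.array([[cfg.sigma_a2_true]]),
                           "sigma_p2_true": REP_COMPONENTS["pe"],
                           "sigma_hys2_true": REP_COMPONENTS["hys"],
                           "sigma_e2_true": (REP_COMPONENTS["residual"],) * N_RES_CLASSES})
    table, ledger = simulate_records(ped, bvs, cfg_rep, rng, trajectory=False, F=F)
    return ped, table, ledger


def simulate_ra_dataset(cfg: SimConfig) -> tuple[Pedigree, pd.DataFrame, TruthLedger]:
    """Pedigree + records generated under the order-2 random-regression model."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    F = inbreeding_meuwissen_luo(ped)
    bvs = simulate_breeding_values(ped, cfg.Ka_true, rng, F)
    table, ledger = simulate_records(ped, bvs, cfg, rng, trajectory=True, F=F)
    return ped, table, ledger


def to_calving_records(table: pd.DataFrame, ped: Pedigree,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, pd.Series]:
    """Raw calving records (cow, calving_date, herd, season) plus birth dates.

    Ages are obtained by inverting the time-ratio Re definition at each
    record's (clipped) Re value, so recomputing Re from the emitted dates
    reproduces the generated phenotype up to the cap.
    """
    birth = {}
    for cow in table["cow"].unique():
        i = ped.loc(cow)
        birth[cow] = (pd.Timestamp(f"{ped.birth_year[i]}-01-01")
                      + pd.Timedelta(days=int(rng.integers(0, 365))))
    birth = pd.Series(birth)
    re_clipped = table["re"].clip(20.0, 100.0)
    optimal = AFC_OPT_MONTHS + (table["cn"] - 1) * CI_OPT_MONTHS
    age_months = 100.0 * optimal / re_clipped
    dates = (birth.loc[table["cow"]].reset_index(drop=True)
             + pd.to_timedelta((age_months * DAYS_PER_MONTH).round().to_numpy(), unit="D"))
    recs = pd.DataFrame({"cow": table["cow"].to_numpy(), "calving_date": dates,
                         "herd": table["herd"].to_numpy(),
                         "season": table["season"].to_numpy()})
    return recs, birth


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None,
                       ipct_genetic: pd.Series | None = None
                       ) -> tuple[GenotypeMatrix, pd.Series, TruthLedger]:
    """Biallelic genotypes with planted causal loci and a pseudo-phenotype.

    Allele frequencies ~ U(0.05, 0.5) with Hardy-Weinberg sampling;
    ``cfg.fst > 0`` splits samples into two Balding-Nichols
    subpopulations.  The pseudo-phenotype is the standardized causal score
    scaled to ``causal_h2`` plus either white noise or (when supplied) the
    standardized ``ipct_genetic`` background.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_markers
    p = rng.uniform(0.05, 0.5, size=m)
    if cfg.fst > 0:
        a = p * (1 - cfg.fst) / cfg.fst
        b = (1 - p) * (1 - cfg.fst) / cfg.fst
        p1, p2 = rng.beta(a, b), rng.beta(a, b)
        half = n // 2
        dos = np.vstack([
            rng.binomial(2, np.clip(p1, 0.001, 0.999), size=(half, m)),
            rng.binomial(2, np.clip(p2, 0.001, 0.999), size=(n - half, m)),
        ]).astype(float)
        subpop = np.array([0] * half + [1] * (n - half))
    else:
        dos = rng.binomial(2, p, size=(n, m)).astype(float)
        subpop = np.zeros(n, dtype=int)

    per_chrom = int(np.ceil(m / cfg.n_chromosomes))
    chroms, positions = [], []
    for c in range(cfg.n_chromosomes):
        k = min(per_chrom, m - c * per_chrom)
        if k <= 0:
            break
        chroms.extend([str(c + 1)] * k)
        positions.extend(np.sort(rng.integers(1, 120_000_000, size=k)))
    bim = pd.DataFrame({"chrom": chroms, "snp": [f"SNP{j + 1:06d}" for j in range(m)],
                        "cm": 0.0, "pos": positions, "a1": "A", "a2": "B"})
    fam = pd.DataFrame({"fid": [f"F{i + 1:04d}" for i in range(n)],
                        "iid": [f"S{i + 1:04d}" for i in range(n)],
                        "father": "0", "mother": "0", "sex": 2, "phenotype": -9})

    causal_idx = rng.choice(m, size=cfg.n_causal, replace=False) if cfg.n_causal else np.array([], int)
    effects = rng.standard_normal(cfg.n_causal)
    if cfg.n_causal and cfg.causal_h2 > 0:
        score = dos[:, causal_idx] @ effects
        score = (score - score.mean()) / score.std()
    else:
        score = np.zeros(n)
    if ipct_genetic is not None:
        bg = np.asarray(ipct_genetic, dtype=float)[:n]
        bg = (bg - bg.mean()) / bg.std()
    else:
        bg = rng.standard_normal(n)
    h2 = cfg.causal_h2
    y = np.sqrt(h2) * score + np.sqrt(1.0 - h2) * bg

    if cfg.missing_rate > 0:
        mask = rng.random(dos.shape) < cfg.missing_rate
        dos[mask] = np.nan

    geno = GenotypeMatrix(dos, bim, fam)
    ledger = TruthLedger(
        variance_components={"causal_h2": h2, "fst": cfg.fst,
                             "subpop": subpop.tolist() if cfg.fst > 0 else None},
        causal_markers=pd.DataFrame({"snp": bim["snp"].iloc[causal_idx].to_numpy(),
                                     "index": causal_idx, "effect": effects}))
    return geno, pd.Series(y, index=fam["iid"].to_numpy(), name="IpcT"), ledger
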