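"""Seeded forward simulator for longitudinal-trait GWAS experiments.

The generator emulates a livestock-style study design:

1. *Historical phase* — Wright-Fisher random mating at constant size for a
   configurable number of generations, starting from founder allele
   frequencies drawn Uniform(0.1, 0.9), to induce drift and realistic
   relatedness.  SNPs segregate independently (the tested methods use the
   pedigree, not LD).
2. *Recorded pedigree* — one expansion generation (the recorded founders),
   then ``n_recent_generations`` of n_sires sires each mated to a share of
   the n_dams dams, two offspring (one male, one female) per dam.  The
   females of the recent generations form the phenotyped cohort.
3. *Phenotypes* — y_i(t) = mu(t) + x_i qtn(t) + a_i(t) + p_i(t) + e_it on a
   shared recording grid.  The QTN effect curve is a smooth order-2
   Legendre combination scaled so its sum over the integer time grid equals
   ``qtn_cumulative`` exactly.  The polygenic trajectories a_i(t) sum the
   centred background-SNP dosages times per-SNP random coefficient
   vectors; polygenic and permanent-environmental scales are calibrated on
   the realized cohort so the time-averaged variance shares hit the
   configured heritability partition, and the total phenotypic variance is
   set by the QTN heritability (the QTN curve itself is never rescaled).

Of the ``n_snps`` simulated SNPs, index 0 is the causal QTN, index 1 the
null-effect SNP used for type-I error, and the remaining ``n_background``
carry the polygenic effects; background genotypes are withheld from the
exported genotype matrix by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import TimeDomain, legendre_matrix
from .data import GenotypeMatrix, LongitudinalData
from .model import ConvergenceError, ModelSpec, RandomRegressionModel
from .pedigree import Pedigree

__all__ = ["SimConfig", "SimTruth", "simulate_population", "qtn_effect_curve",
           "simulate_phenotypes", "simulate_dataset", "run_experiment"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation design parameters (defaults reproduce the study design).

    The default profile phenotypes 2,000 females (500 dams per recent
    generation); ``SimConfig.desk(n)`` scales the cohort down for
    desk-scale experiments while preserving the mating structure.
    """

    n_historical_generations: int = 100
    historical_size: int = 100
    n_sires: int = 50
    n_dams: int = 500
    n_recent_generations: int = 4
    n_snps: int = 1002
    n_background: int = 1000
    n_records: int = 10
    t_min: float = 5.0
    t_max: float = 305.0
    trait_h2: float = 0.3
    pe_proportion: float = 0.2
    qtn_h2: float = 0.01
    qtn_cumulative: float = 175.21
    qtn_freq: float = 0.5
    founder_freq_low: float = 0.1
    founder_freq_high: float = 0.9
    qtn_maf_min: float = 0.1
    qtn_max_retries: int = 50
    # population mean curve mu(t) = c0 + c1 t + c2 t^2 (phenotype units)
    mu_poly: tuple = (20.0, 0.08, -0.00025)
    # unscaled QTN curve shape, normalized-Legendre coefficients (order 2)
    qtn_shape: tuple = (1.0, 0.2, -0.15)
    # relative scale of the order-0..2 polygenic coefficient variances
    polygenic_profile: tuple = (1.0, 0.5, 0.25)
    pe_profile: tuple = (1.0, 0.5, 0.25)

    def __post_init__(self) -> None:
        if not 0 < self.trait_h2 + self.pe_proportion < 1:
            raise ValueError("trait_h2 + pe_proportion must be in (0, 1)")
        if not 0 < self.qtn_h2 < self.trait_h2:
            raise ValueError("qtn_h2 must be in (0, trait_h2)")
        if min(self.n_sires, self.n_dams, self.n_snps, self.n_records) <= 0:
            raise ValueError("all design counts must be positive")
        if self.n_background > self.n_snps - 2:
            raise ValueError("need at least 2 non-background SNPs (QTN + null)")

    @property
    def n_phenotyped(self) -> int:
        return self.n_dams * self.n_recent_generations

    @property
    def domain(self) -> TimeDomain:
        return TimeDomain(self.t_min, self.t_max)

    @property
    def record_times(self) -> np.ndarray:
        return np.round(np.linspace(self.t_min, self.t_max, self.n_records))

    @classmethod
    def full(cls, **kw) -> "SimConfig":
        return cls(**kw)

    @classmethod
    def desk(cls, n_phenotyped: int = 500, **kw) -> "SimConfig":
        """Scaled-down profile: n_phenotyped cohort, 1:10 sire:dam ratio."""
        n_dams = max(n_phenotyped // 4, 4)
        n_sires = max(n_dams // 10, 2)
        return cls(n_sires=n_sires, n_dams=n_dams, **kw)

    def mu_curve(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        c0, c1, c2 = self.mu_poly
        return c0 + c1 * t + c2 * t**2


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    qtn_id: str
    null_id: str
    qtn_curve_grid: np.ndarray        # effect per copy on the integer grid
    qtn_curve_records: np.ndarray     # effect per copy at the record times
    cumulative_effect: float
    qtn_freq: float
    genetic_values: np.ndarray        # (n_phen, T) true a_i(t) + x_i qtn(t)
    pe_values: np.ndarray             # (n_phen, T)
    sigma_p2: float
    sigma_e2: float
    variance_partition: dict


def qtn_effect_curve(cfg: SimConfig, domain: TimeDomain | None = None) -> np.ndarray:
    """Per-allele QTN effect curve on the integer grid, scaled so the grid
    sum equals ``cfg.qtn_cumulative`` exactly (invariant to the overall
    scale of the configured shape coefficients)."""
    domain = domain if domain is not None else cfg.domain
    grid = domain.grid.astype(float)
    shape = np.asarray(cfg.qtn_shape, dtype=float)
    phi = legendre_matrix(len(shape) - 1, grid, domain)
    base = phi @ shape
    total = base.sum()
    if abs(total) < 1e-12:
        raise ValueError("QTN shape sums to zero over the grid and cannot be scaled")
    return base * (cfg.qtn_cumulative / total)


def _mendelian_cross(g_sire, g_dam, rng):
    """Offspring dosages from parent dosage rows (independent loci)."""
    gam_s = (rng.random(g_sire.shape) < g_sire / 2.0).astype(np.int8)
    gam_d = (rng.random(g_dam.shape) < g_dam / 2.0).astype(np.int8)
    return gam_s + gam_d


def simulate_population(cfg: SimConfig, seed: int):
    """Forward-simulate the pedigree and SNP genotypes.

    Returns (Pedigree, GenotypeMatrix over all recorded individuals and all
    n_snps SNPs, phenotyped_ids).  The QTN (SNP index 0) starts at frequency
    ``qtn_freq`` and is re-dropped through the same parentage (bounded
    retries) if it drifts below ``qtn_maf_min`` in the phenotyped cohort;
    the null SNP (index 1) is treated the same so both remain testable.
    """
    rng = np.random.default_rng(seed)
    S = cfg.n_snps
    N = cfg.historical_size

    freqs = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, S)
    freqs[0] = cfg.qtn_freq
    freqs[1] = cfg.qtn_freq
    geno = (rng.random((N, S)) < freqs).astype(np.int8) + (
        rng.random((N, S)) < freqs
    ).astype(np.int8)
    sex = np.tile([0, 1], N // 2 + 1)[:N]  # 0 male, 1 female

    # historical random mating at constant size; parentage retained so that
    # individual SNPs can be re-dropped through the same family structure
    hist_parents = []
    for _ in range(cfg.n_historical_generations):
        males = np.flatnonzero(sex == 0)
        females = np.flatnonzero(sex == 1)
        sires = rng.choice(males, N)
        dams = rng.choice(females, N)
        geno = _mendelian_cross(geno[sires], geno[dams], rng)
        hist_parents.append((sires, dams))
        sex = np.tile([0, 1], N // 2 + 1)[:N]

    # expansion generation = recorded founders (half male, half female)
    n0 = 2 * cfg.n_dams
    males = np.flatnonzero(sex == 0)
    females = np.flatnonzero(sex == 1)
    sires0 = rng.choice(males, n0)
    dams0 = rng.choice(females, n0)
    geno0 = _mendelian_cross(geno[sires0], geno[dams0], rng)
    founder_cross = (sires0, dams0)

    ids = [f"G0_{i}" for i in range(n0)]
    records = [(v, None, None) for v in ids]
    sex0 = np.tile([0, 1], n0 // 2 + 1)[:n0]
    all_geno = [geno0]
    gen_ids = ids
    gen_sex = sex0
    gen_geno = geno0
    phenotyped = []
    recent_parents = []

    for g in range(1, cfg.n_recent_generations + 1):
        males = np.flatnonzero(gen_sex == 0)
        females = np.flatnonzero(gen_sex == 1)
        sires = rng.choice(males, cfg.n_sires, replace=False)
        dams = females[:cfg.n_dams]
        dam_sire = rng.choice(sires, cfg.n_dams)  # one sire per dam
        child_ids, child_sex, sire_idx, dam_idx = [], [], [], []
        for j, (dm, sr) in enumerate(zip(dams, dam_sire)):
            for off, sx in ((0, 0), (1, 1)):  # one male, one female per dam
                child_ids.append(f"G{g}_{2 * j + off}")
                child_sex.append(sx)
                sire_idx.append(sr)
                dam_idx.append(dm)
        sire_idx = np.asarray(sire_idx)
        dam_idx = np.asarray(dam_idx)
        child_geno = _mendelian_cross(gen_geno[sire_idx], gen_geno[dam_idx], rng)
        records += [
            (cid, gen_ids[s], gen_ids[d])
            for cid, s, d in zip(child_ids, sire_idx, dam_idx)
        ]
        recent_parents.append((sire_idx, dam_idx))
        phenotyped += [cid for cid, sx in zip(child_ids, child_sex) if sx == 1]
        all_geno.append(child_geno)
        gen_ids, gen_sex, gen_geno = child_ids, np.asarray(child_sex), child_geno

    ped = Pedigree.from_records(records)
    full_ids = np.concatenate([[f"G0_{i}" for i in range(n0)]] + [
        [f"G{g}_{j}" for j in range(2 * cfg.n_dams)]
        for g in range(1, cfg.n_recent_generations + 1)
    ]).astype(object)
    full_geno = np.vstack(all_geno).astype(float)

    # keep the QTN and the null SNP testable: re-drop through the stored
    # parentage with fresh Mendelian sampling if drift took them too far
    phen_rows = pd.Index(full_ids).get_indexer(phenotyped)
    for snp in (0, 1):
        col = full_geno[:, snp]
        for attempt in range(cfg.qtn_max_retries):
            f = col[phen_rows].mean() / 2.0
            if cfg.qtn_maf_min <= f <= 1 - cfg.qtn_maf_min:
                break
            col = _redrop_snp(cfg, rng, hist_parents, founder_cross,
                              recent_parents, n0)
        else:
            warnings.warn(
                f"SNP {snp} stayed outside MAF bounds after "
                f"{cfg.qtn_max_retries} re-drops; using the last draw"
            )
        full_geno[:, snp] = col

    n_extra = cfg.n_snps - 2 - cfg.n_background
    snp_ids = np.array(
        ["QTN", "NULL"]
        + [f"BG{i}" for i in range(cfg.n_background)]
        + [f"NULL{i}" for i in range(n_extra)],
        dtype=object,
    )
    gm = GenotypeMatrix(snp_ids, full_ids, full_geno.T)
    return ped, gm, np.asarray(phenotyped, dtype=object)


def _redrop_snp(cfg, rng, hist_parents, founder_cross, recent_parents, n0):
    """Gene-drop a single locus (founder frequency qtn_freq) through the
    already-sampled parentage of the whole simulation."""
    N = cfg.historical_size
    g = (rng.random(N) < cfg.qtn_freq).astype(np.int8) + (
        rng.random(N) < cfg.qtn_freq
    ).astype(np.int8)
    for sires, dams in hist_parents:
        g = _mendelian_cross(g[sires, None], g[dams, None], rng).ravel()
    sires0, dams0 = founder_cross
    g0 = _mendelian_cross(g[sires0, None], g[dams0, None], rng).ravel()
    out = [g0]
    gen = g0
    for sire_idx, dam_idx in recent_parents:
        gen = _mendelian_cross(gen[sire_idx, None], gen[dam_idx, None], rng).ravel()
        out.append(gen)
    return np.concatenate(out).astype(float)


def simulate_phenotypes(ped: Pedigree, geno: GenotypeMatrix, phenotyped_ids,
                        cfg: SimConfig, seed: int):
    """Simulate longitudinal records for the phenotyped cohort.

    Returns (LongitudinalData, SimTruth).  See the module docstring for the
    generative model and the variance calibration.
    """
    rng = np.random.default_rng(seed)
    domain = cfg.domain
    rec_t = cfg.record_times.astype(float)
    T = len(rec_t)
    n = len(phenotyped_ids)

    gsub = geno.subset_individuals(phenotyped_ids)
    x_qtn = gsub.values[0]
    qtn_grid = qtn_effect_curve(cfg, domain)
    phi_grid = legendre_matrix(len(cfg.qtn_shape) - 1, domain.grid.astype(float), domain)
    # express the scaled curve back in coefficient space for record times
    coefs = np.linalg.lstsq(phi_grid, qtn_grid, rcond=None)[0]
    phi_rec = legendre_matrix(len(cfg.qtn_shape) - 1, rec_t, domain)
    qtn_rec = phi_rec @ coefs

    # total phenotypic variance implied by the fixed QTN curve and qtn_h2
    var_x = float(np.var(x_qtn))
    if var_x == 0:
        raise ValueError("monomorphic QTN in the phenotyped cohort")
    var_qtn_t = var_x * qtn_rec**2
    sigma_p2 = float(np.mean(var_qtn_t)) / cfg.qtn_h2

    # polygenic trajectories from the background SNPs
    bg = gsub.values[2:2 + cfg.n_background]
    bg_centered = bg - bg.mean(axis=1, keepdims=True)
    k = len(cfg.polygenic_profile)
    alpha = rng.normal(size=(cfg.n_background, k)) * np.sqrt(cfg.polygenic_profile)
    a_coef = bg_centered.T @ alpha                     # (n, k)
    phi_bg = legendre_matrix(k - 1, rec_t, domain)
    a_vals = a_coef @ phi_bg.T                         # (n, T)
    target_poly = (cfg.trait_h2 - cfg.qtn_h2) * sigma_p2
    realized = float(np.mean(np.var(a_vals, axis=0)))
    a_vals *= np.sqrt(target_poly / realized)
    a_coef *= np.sqrt(target_poly / realized)

    # permanent environmental trajectories
    kp = len(cfg.pe_profile)
    pe_coef = rng.normal(size=(n, kp)) * np.sqrt(cfg.pe_profile)
    phi_pe = legendre_matrix(kp - 1, rec_t, domain)
    pe_vals = pe_coef @ phi_pe.T
    target_pe = cfg.pe_proportion * sigma_p2
    pe_vals *= np.sqrt(target_pe / float(np.mean(np.var(pe_vals, axis=0))))

    sigma_e2 = (1.0 - cfg.trait_h2 - cfg.pe_proportion) * sigma_p2
    noise = rng.normal(scale=np.sqrt(sigma_e2), size=(n, T))

    qtn_effect = np.outer(x_qtn, qtn_rec)
    mu = cfg.mu_curve(rec_t)
    Y = mu[None, :] + qtn_effect + a_vals + pe_vals + noise

    ids = np.repeat(np.asarray(phenotyped_ids, dtype=object), T)
    times = np.tile(rec_t, n)
    data = LongitudinalData(ids, times, Y.ravel())

    genetic = qtn_effect + a_vals
    truth = SimTruth(
        qtn_id="QTN",
        null_id="NULL",
        qtn_curve_grid=qtn_grid,
        qtn_curve_records=qtn_rec,
        cumulative_effect=float(qtn_grid.sum()),
        qtn_freq=float(np.mean(x_qtn) / 2.0),
        genetic_values=genetic,
        pe_values=pe_vals,
        sigma_p2=sigma_p2,
        sigma_e2=sigma_e2,
        variance_partition={
            "genetic": float(np.mean(np.var(genetic, axis=0)) / sigma_p2),
            "qtn": float(np.mean(np.var(qtn_effect, axis=0)) / sigma_p2),
            "pe": float(np.mean(np.var(pe_vals, axis=0)) / sigma_p2),
            "residual": sigma_e2 / sigma_p2,
        },
    )
    return data, truth


def simulate_dataset(cfg: SimConfig, seed: int, keep_background: bool = False):
    """One full replicate: population, genotypes and phenotypes.

    Returns (Pedigree, GenotypeMatrix, LongitudinalData, SimTruth).  Unless
    ``keep_background``, only the QTN and the null SNP are exported (the
    background genotypes exist solely to generate the polygenic effects).
    """
    ped, gm, phen_ids = simulate_population(cfg, seed)
    data, truth = simulate_phenotypes(ped, gm, phen_ids, cfg, seed + 2**20)
    if not keep_background:
        # export the QTN, the null SNP, and any surplus SNPs beyond the
        # polygenic background (surplus SNPs carry no effect, so a config
        # with n_snps > n_background + 2 yields extra null markers)
        keep = [0, 1] + list(range(2 + cfg.n_background, cfg.n_snps))
        gm = GenotypeMatrix(gm.snp_ids[keep], gm.individual_ids, gm.values[keep])
    return ped, gm, data, truth


# ---------------------------------------------------------------------------
# Replicate-level experiment runner
# ---------------------------------------------------------------------------

ALL_METHODS = ("fgwas-c", "fgwas-f", "ebv-p", "ebv-np", "drp-p", "drp-np", "residual")


def run_experiment(
    cfg: SimConfig,
    n_reps: int,
    methods=ALL_METHODS,
    alphas=(0.05, 0.01),
    base_seed: int = 1,
    fit_spec: ModelSpec | None = None,
) -> dict:
    """Replicate the power / type-I-error / estimation-accuracy experiment.

    Per replicate (seed = base_seed + replicate index): simulate a dataset,
    fit the reduced model by REML, run every requested scan on the causal
    QTN and the null SNP, and record p-values and cumulative-effect
    estimates.  Returns a dict with the per-replicate table (``detail``),
    the power/FPR summary per method and alpha (``rates``), the
    estimation-accuracy summary (``estimates``: mean, SD, RMSE against the
    true cumulative effect), and the number of failed replicates.
    """
    from .baselines import (accumulate_ebv, average_residuals, deregress,
                            reliabilities, scan_single_value)

    fit_spec = fit_spec if fit_spec is not None else ModelSpec(2, 2, 2)
    rows = []
    failures = 0
    for rep in range(n_reps):
        seed = base_seed + rep
        try:
            ped, gm, data, truth = simulate_dataset(cfg, seed)
            model = RandomRegressionModel(data, fit_spec, ped, cfg.domain)
            res = model.fit()
            rows += _replicate_rows(rep, res, gm, truth, methods)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"replicate {rep} failed: {exc}")
            failures += 1
            continue
    detail = pd.DataFrame(rows)
    true_cum = float(cfg.qtn_cumulative)

    rate_rows, est_rows = [], []
    for method in methods:
        sub = detail[detail["method"] == method]
        qtn = sub[sub["snp"] == "QTN"]
        null = sub[sub["snp"] == "NULL"]
        for alpha in alphas:
            rate_rows.append({
                "method": method, "alpha": alpha,
                "power": float((qtn["p"] < alpha).mean()) if len(qtn) else np.nan,
                "fpr": float((null["p"] < alpha).mean()) if len(null) else np.nan,
            })
        est = qtn["estimate"].to_numpy(dtype=float)
        est = est[np.isfinite(est)]
        if len(est):
            bias = est.mean() - true_cum
            est_rows.append({
                "method": method,
                "mean": float(est.mean()),
                "sd": float(est.std(ddof=1)) if len(est) > 1 else np.nan,
                "rmse": float(np.sqrt(np.mean((est - true_cum) ** 2))),
                "bias": float(bias),
                "n": len(est),
            })
        if method == "fgwas-f":
            dom = qtn["estimate_dom"].to_numpy(dtype=float)
            dom = dom[np.isfinite(dom)]
            if len(dom):
                est_rows.append({
                    "method": "fgwas-f (dominance)",
                    "mean": float(dom.mean()),
                    "sd": float(dom.std(ddof=1)) if len(dom) > 1 else np.nan,
                    "rmse": float(np.sqrt(np.mean(dom**2))),
                    "bias": float(dom.mean()),
                    "n": len(dom),
                })
    return {
        "detail": detail,
        "rates": pd.DataFrame(rate_rows),
        "estimates": pd.DataFrame(est_rows),
        "n_failed": failures,
        "true_cumulative": true_cum,
    }


def _replicate_rows(rep, res, gm, truth, methods):
    from .baselines import (accumulate_ebv, average_residuals, deregress,
                            reliabilities, scan_single_value)

    rows = []

    def emit(method, table, est_col="cumulative_add", dom_col=None):
        for _, r in table.iterrows():
            rows.append({
                "rep": rep, "method": method, "snp": r["snp"],
                "p": float(r["p"]), "W": float(r["W"]),
                "estimate": float(r[est_col]) if est_col in r else np.nan,
                "estimate_dom": float(r[dom_col]) if dom_col else np.nan,
            })

    need_pseudo = any(m in methods for m in ("ebv-p", "ebv-np", "drp-p", "drp-np"))
    if "fgwas-c" in methods:
        emit("fgwas-c", res.scan(gm, model="fgwas-c").table)
    if "fgwas-f" in methods:
        emit("fgwas-f", res.scan(gm, model="fgwas-f").table,
             dom_col="cumulative_dom")
    if need_pseudo:
        ebv = accumulate_ebv(res)
    if "ebv-p" in methods:
        emit("ebv-p", scan_single_value(ebv, gm, res, fit_polygenic=True),
             est_col="coef")
    if "ebv-np" in methods:
        emit("ebv-np", scan_single_value(ebv, gm, fit_polygenic=False),
             est_col="coef")
    if "drp-p" in methods or "drp-np" in methods:
        r2 = reliabilities(res)
        ebv_all = accumulate_ebv(res, include_ancestors=True)
        drp = deregress(ebv, res.model.pedigree, r2, ebv_all=ebv_all)
        if "drp-p" in methods:
            emit("drp-p", scan_single_value(drp, gm, res, fit_polygenic=True),
                 est_col="coef")
        if "drp-np" in methods:
            emit("drp-np", scan_single_value(drp, gm, fit_polygenic=False),
                 est_col="coef")
    if "residual" in methods:
        resid = average_residuals(res)
        emit("residual", scan_single_value(resid, gm, fit_polygenic=False),
             est_col="coef")
    return rows
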