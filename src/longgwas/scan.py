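"""Time-varied SNP association scans: fGWAS-C and fGWAS-F.

Both scans augment the fitted random regression model with fixed
time-varied SNP terms and test them with the incremental Wald statistic

    W = [R(full) - R(reduced)] / sigma_e_hat^2  ~  chi^2_{df_w},

where R(model) is the reduction in sums of squares and variance components
are plugged in from the reduced (no-SNP) model.

* fGWAS-C fits the dosage x_i in {0,1,2} (or continuous in [0,2]) times a
  Legendre curve SNP(t) = sum_k eta_k phi_k(t); df_w = nf + 1.
* fGWAS-F fits one curve per observed genotype class (reference = lowest
  genotype, absorbed into mu(t)); df_w = (#classes - 1)(nf + 1).

The fGWAS-F class curves decompose into additive and dominance effect
curves, add(t) = [SNP_AA(t) - SNP_aa(t)]/2 and
dom(t) = SNP_Aa(t) - [SNP_AA(t) + SNP_aa(t)]/2, and the per-SNP additive
variance sigma^2_{a,SNP}(t) = 2pq [add(t) + dom(t)(q - p)]^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import TimeDomain, legendre_matrix
from .data import GenotypeMatrix, LongitudinalData
from .model import FixedGroup, RRMResults, RandomRegressionModel

__all__ = [
    "wald_incremental",
    "cumulative_effect",
    "decompose_fgwas_f",
    "scan_fgwas_c",
    "scan_fgwas_f",
    "ScanResult",
]


def wald_incremental(rss_full: float, rss_reduced: float, sigma_e2: float, df: int):
    """Incremental Wald statistic and chi-square p-value.

    W = (rss_full - rss_reduced) / sigma_e2, clipped at zero (a tiny
    negative difference is numerical noise and is tolerated up to 1e-8
    relative).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be > 0")
    diff = rss_full - rss_reduced
    slack = 1e-8 * max(abs(rss_full), 1.0)
    if diff < -slack:
        warnings.warn(
            f"R(full) < R(reduced) by {-diff:.3g}; Wald statistic clipped at 0"
        )
    W = max(diff, 0.0) / sigma_e2
    p = float(stats.chi2.sf(W, df)) if W > 0 else 1.0
    return float(W), p


def accumulation_vector(order: int, domain: TimeDomain) -> np.ndarray:
    """Q_c = sum over the integer grid t_min..t_max of the basis rows."""
    phi = legendre_matrix(order, domain.grid.astype(float), domain)
    return phi.sum(axis=0)


def cumulative_effect(coefs, domain: TimeDomain) -> float:
    """Sum of the curve sum_k coef_k phi_k(t) over the integer time grid."""
    coefs = np.asarray(coefs, dtype=float)
    return float(accumulation_vector(len(coefs) - 1, domain) @ coefs)


@dataclass
class SnpEffectCurves:
    """Estimated SNP effect curves (coefficient scale).

    For fGWAS-C only ``eta`` is set; for fGWAS-F the per-genotype-class
    coefficient vectors (reference class all-zero) are stored in
    ``lambdas`` keyed by genotype 0 (aa), 1 (Aa), 2 (AA).
    """

    order: int
    domain: TimeDomain
    eta: np.ndarray | None = None
    lambdas: dict | None = None

    def curve(self, coefs, times) -> np.ndarray:
        return legendre_matrix(self.order, times, self.domain) @ np.asarray(coefs)

    def add_curve(self, times) -> np.ndarray:
        if self.eta is not None:
            return self.curve(self.eta, times)
        return (self.curve(self.lambdas[2], times) - self.curve(self.lambdas[0], times)) / 2.0

    def dom_curve(self, times, convention: str = "midpoint") -> np.ndarray:
        if self.eta is not None:
            return np.zeros(len(np.atleast_1d(times)))
        aa = self.curve(self.lambdas[0], times)
        Aa = self.curve(self.lambdas[1], times)
        AA = self.curve(self.lambdas[2], times)
        if convention == "midpoint":
            return Aa - (AA + aa) / 2.0
        if convention == "printed":
            return Aa - (AA - aa) / 2.0
        raise ValueError(f"unknown dominance convention {convention!r}")


def decompose_fgwas_f(curves: SnpEffectCurves, p: float, domain: TimeDomain,
                      convention: str = "midpoint"):
    """Additive/dominance/variance curves on the integer grid.

    add(t) = [SNP_AA(t) - SNP_aa(t)]/2, dom(t) per the chosen convention,
    sigma^2_{a,SNP}(t) = 2 p q [add(t) + dom(t)(q - p)]^2 with q = 1 - p.
    Raises for monomorphic frequencies (p in {0, 1}).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    t = domain.grid.astype(float)
    add = curves.add_curve(t)
    dom = curves.dom_curve(t, convention)
    q = 1.0 - p
    var = 2.0 * p * q * (add + dom * (q - p)) ** 2
    return add, dom, var


@dataclass
class ScanResult:
    """Per-SNP scan results: table plus the estimated effect curves."""

    table: pd.DataFrame
    curves: list = field(default_factory=list)
    model: str = "fgwas-c"
    domain: TimeDomain | None = None

    def __len__(self) -> int:
        return len(self.table)


def _aligned_dosages(results: RRMResults, geno: GenotypeMatrix) -> GenotypeMatrix:
    ids = results.model.data.individuals
    missing = set(ids) - set(geno.individual_ids)
    if missing:
        raise ValueError(
            f"{len(missing)} phenotyped individual(s) missing from genotypes"
        )
    return geno.subset_individuals(ids)


def _model_phen_var(results: RRMResults, times) -> np.ndarray:
    """Model-implied phenotypic variance curve (per-time)."""
    m = results.model
    phi_a = legendre_matrix(m.spec.nr1, times, m.domain)
    phi_p = legendre_matrix(m.spec.nr2, times, m.domain)
    return (
        np.einsum("ta,ab,tb->t", phi_a, results.vc.G, phi_a)
        + np.einsum("ta,ab,tb->t", phi_p, results.vc.P, phi_p)
        + results.vc.sigma_e2
    )


def _scan_common(results, geno, snp_builder, maf_min):
    """Shared per-SNP driver: builds SNP fixed groups, computes incremental
    Wald tests against the reduced fit, and assembles the result table."""
    model = results.model
    kern = model.kernel()
    vc = results.vc
    ctx = kern._prepare(vc)
    mean_group = kern.mean_group()
    red = kern.gls(vc, [mean_group], ctx=ctx)
    rss_red = red["rss"]
    domain = model.domain
    grid = domain.grid.astype(float)
    var_p = _model_phen_var(results, grid)

    rows, curve_objs = [], []
    freqs = geno.freq
    for s in range(geno.n_snps):
        x = geno.values[s]
        p_freq = freqs[s]
        rec = {
            "snp": geno.snp_ids[s],
            "chrom": geno.chrom[s] if geno.chrom is not None else "",
            "pos": geno.pos[s] if geno.pos is not None else 0,
            "freq": p_freq,
        }
        maf = min(p_freq, 1 - p_freq) if np.isfinite(p_freq) else 0.0
        if maf <= 0 or np.nanstd(x) == 0:
            rows.append({**rec, "df": 0, "W": 0.0, "p": 1.0, "testable": False,
                         "cumulative_add": np.nan, "cumulative_dom": np.nan,
                         "mean_qtn_h2": np.nan})
            curve_objs.append(None)
            continue
        if maf < maf_min:
            rows.append({**rec, "df": 0, "W": 0.0, "p": 1.0, "testable": False,
                         "cumulative_add": np.nan, "cumulative_dom": np.nan,
                         "mean_qtn_h2": np.nan})
            curve_objs.append(None)
            continue
        try:
            out = snp_builder(kern, ctx, mean_group, x, rss_red, red)
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"SNP {rec['snp']}: rank-deficient design ({exc}); skipped")
            rows.append({**rec, "df": 0, "W": 0.0, "p": 1.0, "testable": False,
                         "cumulative_add": np.nan, "cumulative_dom": np.nan,
                         "mean_qtn_h2": np.nan})
            curve_objs.append(None)
            continue
        curves, rss_full, df, rss_red_s = out
        W, pval = wald_incremental(rss_full, rss_red_s, vc.sigma_e2, df)
        add, dom, var_snp = _curves_on_grid(curves, p_freq, domain)
        rows.append({
            **rec, "df": df, "W": W, "p": pval, "testable": True,
            "cumulative_add": float(add.sum()),
            "cumulative_dom": float(dom.sum()),
            "mean_qtn_h2": float(np.mean(var_snp / var_p)),
        })
        curve_objs.append(curves)
    table = pd.DataFrame(rows)
    _attach_coefficients(table, curve_objs, results.spec.nf)
    return table, curve_objs


def _curves_on_grid(curves: SnpEffectCurves, p_freq: float, domain: TimeDomain):
    t = domain.grid.astype(float)
    if curves.eta is not None:
        add = curves.curve(curves.eta, t)
        dom = np.zeros_like(add)
        q = 1 - p_freq
        var = 2 * p_freq * q * add**2
        return add, dom, var
    return decompose_fgwas_f(curves, p_freq, domain)


def _attach_coefficients(table, curve_objs, nf):
    k = nf + 1
    cols = {}
    for ci in range(k):
        cols[f"eta_{ci}"] = [
            (c.eta[ci] if c is not None and c.eta is not None else np.nan)
            for c in curve_objs
        ]
    for cls, name in ((0, "aa"), (1, "Aa"), (2, "AA")):
        for ci in range(k):
            cols[f"lambda_{name}_{ci}"] = [
                (c.lambdas[cls][ci]
                 if c is not None and c.lambdas is not None and cls in c.lambdas
                 else np.nan)
                for c in curve_objs
            ]
    for name, vals in cols.items():
        table[name] = vals


def scan_fgwas_c(results: RRMResults, geno: GenotypeMatrix,
                 maf_min: float = 0.01) -> ScanResult:
    """fGWAS-C scan: per-SNP time-varied dosage regression.

    Variance components are plugged in from the reduced fit in ``results``.
    Missing genotypes are mean-imputed per SNP; monomorphic or
    low-MAF SNPs are flagged untestable (W = 0, p = 1).  Accepts hard calls
    or continuous dosages in [0, 2].
    """
    geno = _aligned_dosages(results, geno)
    nf = results.spec.nf
    kern0 = results.model.kernel()
    phi_f = kern0.phi_f

    def builder(kern, ctx, mean_group, x, rss_red, red):
        x = x.copy()
        nanmask = np.isnan(x)
        if nanmask.any():
            x[nanmask] = np.nanmean(x)
        snp_group = FixedGroup("snp", x, phi_f)
        out = kern.gls(results.vc, [mean_group, snp_group], ctx=ctx)
        eta = out["beta"][out["offsets"][1]:out["offsets"][2]]
        curves = SnpEffectCurves(nf, results.model.domain, eta=eta)
        return curves, out["rss"], nf + 1, rss_red

    table, curve_objs = _scan_common(results, geno, builder, maf_min)
    return ScanResult(table, curve_objs, "fgwas-c", results.model.domain)


def scan_fgwas_f(results: RRMResults, geno: GenotypeMatrix,
                 maf_min: float = 0.01,
                 dominance_convention: str = "midpoint") -> ScanResult:
    """fGWAS-F scan: one effect curve per observed genotype class.

    Requires hard genotype calls (0/1/2); dosage input raises with a pointer
    to fGWAS-C.  Individuals with a missing call are dropped for that SNP
    (the reduced-model R is recomputed on the same subset so the Wald
    difference stays valid).  Single-class SNPs are untestable.
    """
    geno = _aligned_dosages(results, geno)
    vals = geno.values[~np.isnan(geno.values)]
    if not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
        raise ValueError(
            "fGWAS-F requires hard genotype calls 0/1/2; "
            "use fGWAS-C for dosage data"
        )
    nf = results.spec.nf
    model = results.model
    kern0 = model.kernel()
    phi_f = kern0.phi_f

    def builder(kern, ctx, mean_group, x, rss_red, red):
        nanmask = np.isnan(x)
        if nanmask.any():
            sub_ids = model.data.individuals[~nanmask]
            sub = _subset_data(model.data, set(sub_ids))
            sub_model = RandomRegressionModel(sub, model.spec, model.pedigree,
                                              model.domain)
            kern = sub_model.kernel()
            ctx = kern._prepare(results.vc)
            mean_group = kern.mean_group()
            rss_red = kern.gls(results.vc, [mean_group], ctx=ctx)["rss"]
            x = x[~nanmask]
        classes = sorted(int(v) for v in np.unique(x))
        if len(classes) < 2:
            raise np.linalg.LinAlgError("single genotype class")
        ref = classes[0]
        groups = [mean_group]
        for cls in classes[1:]:
            groups.append(FixedGroup(f"class{cls}", (x == cls).astype(float), phi_f))
        out = kern.gls(results.vc, groups, ctx=ctx)
        offs = out["offsets"]
        lambdas = {cls: np.zeros(nf + 1) for cls in classes}
        for gi, cls in enumerate(classes[1:], start=1):
            lambdas[cls] = out["beta"][offs[gi]:offs[gi + 1]]
        # unobserved classes: linear interpolation on dosage for the additive
        # contrast; flag by filling with the additive expectation
        if 1 not in lambdas and 0 in lambdas and 2 in lambdas:
            lambdas[1] = (lambdas[0] + lambdas[2]) / 2.0
        if 0 not in lambdas:
            lambdas.setdefault(0, np.zeros(nf + 1))
        if 2 not in lambdas:
            # two observed classes including Aa: treat the observed span as
            # one allele substitution
            lambdas[2] = 2.0 * lambdas[1] - lambdas[0]
        df = (len(classes) - 1) * (nf + 1)
        curves = SnpEffectCurves(nf, model.domain, lambdas=lambdas)
        return curves, out["rss"], df, rss_red

    table, curve_objs = _scan_common(results, geno, builder, maf_min)
    # recompute dominance with the requested convention
    for i, c in enumerate(curve_objs):
        if c is None or not table.loc[i, "testable"]:
            continue
        t = results.model.domain.grid.astype(float)
        dom = c.dom_curve(t, dominance_convention)
        table.loc[i, "cumulative_dom"] = float(dom.sum())
    return ScanResult(table, curve_objs, "fgwas-f", results.model.domain)


def _subset_data(data: LongitudinalData, keep: set) -> LongitudinalData:
    mask = np.array([v in keep for v in data.ids])
    return LongitudinalData(data.ids[mask], data.times[mask], data.values[mask])
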