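"""Multiple-testing thresholds and result tables.

Genome-wide significance uses the Bonferroni threshold alpha / N; false
discovery rates use Storey q-values with the smoother estimate of pi0
(falling back to pi0 = 1, i.e. Benjamini-Hochberg, for small scans).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["bonferroni_threshold", "qvalues", "SignificanceReport",
           "significance_report", "write_scan_table"]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated by the smoother method over lambda = 0.05..0.95 for
    scans of at least 100 tests; otherwise (or when the estimate is
    unstable) pi0 = 1, which reduces to Benjamini-Hochberg step-up.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-d array")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if pi0 is None:
        pi0 = _estimate_pi0(p) if m >= 100 else 1.0
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _estimate_pi0(p: np.ndarray) -> float:
    """Smoother pi0 estimate: cubic fit of pi0(lambda), evaluated at 0.95."""
    lams = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0s = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lams])
    try:
        coefs = np.polyfit(lams, pi0s, 3)
        pi0 = float(np.polyval(coefs, lams[-1]))
    except np.linalg.LinAlgError:
        pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = 1.0
    return min(pi0, 1.0)


@dataclass
class SignificanceReport:
    """Per-SNP significance flags at Bonferroni and q-value thresholds."""

    table: pd.DataFrame
    alpha: float
    bonferroni: float
    q_threshold: float


def significance_report(scan_table: pd.DataFrame, alpha: float = 0.05,
                        q_threshold: float = 0.05) -> SignificanceReport:
    """Attach Bonferroni and q-value significance flags to a scan table."""
    if len(scan_table) == 0:
        raise ValueError("empty scan table")
    tab = scan_table.copy()
    n_tests = int(tab["testable"].sum()) if "testable" in tab else len(tab)
    n_tests = max(n_tests, 1)
    thr = bonferroni_threshold(alpha, n_tests)
    tab["bonferroni_significant"] = tab["p"] < thr
    tab["q"] = qvalues(np.clip(tab["p"].to_numpy(), 1e-300, 1.0))
    tab["q_significant"] = tab["q"] < q_threshold
    return SignificanceReport(tab, alpha, thr, q_threshold)


def write_scan_table(report: SignificanceReport, path, seed=None,
                     config_hash=None) -> None:
    """Write a scan table as TSV with a '#'-prefixed provenance header.

    Rows are sorted by (chrom, pos) when positions are present, input order
    otherwise; two runs from the same seed produce byte-identical files.
    """
    from . import __version__

    tab = report.table
    if len(tab) == 0:
        raise ValueError("refusing to write an empty scan table")
    if "chrom" in tab.columns and "pos" in tab.columns and tab["pos"].abs().sum() > 0:
        tab = tab.sort_values(["chrom", "pos"], kind="mergesort")
    header = [
        f"# longgwas {__version__}",
        f"# alpha={report.alpha} bonferroni={report.bonferroni:.6g} "
        f"q_threshold={report.q_threshold}",
    ]
    if seed is not None:
        header.append(f"# seed={seed}")
    if config_hash is not None:
        header.append(f"# config={config_hash}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        tab.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def config_digest(obj) -> str:
    """Short stable hash of a configuration mapping (provenance header)."""
    text = repr(sorted(vars(obj).items() if hasattr(obj, "__dict__") else obj.items()))
    return hashlib.sha1(text.encode()).hexdigest()[:12]
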