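"""Per-site transmission-disequilibrium statistics on imputed dosages.

Two tests are provided at every panel site.  The paired test is the
exact-form conditional-likelihood TDT on (transmitted, un-transmitted)
dosage pairs: with NUM = sum rho (1 - pi) and DEN = NUM + sum pi (1 - rho),
beta = logit(NUM/DEN), var(beta) = DEN / (NUM (DEN - NUM)) and
X = beta^2 / var(beta) ~ chi2_1 under transmission equilibrium.  The
unpaired alternative is a marginal-homogeneity test on the expected 2x2
table A-D of parental-allele configurations.  The scan applies case-MAF and
INFO filters (defaults 0.01 and 0.3), reports the genomic inflation factor
lambda = median(X)/median(chi2_1), and can apply genomic control.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .dosage_engine import DosageTable, build_dosage_table
from .ls_hmm import HmmParams
from .panel_io import HaplotypePanel, TargetHaplotypes

logger = logging.getLogger("surfbat")

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...

#: reporting-only annotation thresholds (never filters)
GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5


@dataclass(frozen=True)
class PairedResult:
    num: float
    den: float
    beta: float
    var_beta: float
    x: float
    p: float
    degenerate: bool


@dataclass(frozen=True)
class UnpairedResult:
    a: float
    b: float
    c: float
    d: float
    x: float
    p: float
    degenerate: bool


def _check_doses(rho: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rho = np.asarray(rho, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if rho.shape != pi.shape or rho.size < 1:
        raise ValueError("need matched, non-empty rho/pi dose vectors")
    if np.any((rho < 0) | (rho > 1) | (pi < 0) | (pi > 1)):
        raise ValueError("doses must lie in [0, 1]")
    return rho, pi


def paired_tdt(rho, pi, haldane: bool = False) -> PairedResult:
    """Conditional-likelihood TDT on one site's (rho, pi) pairs.

    ``haldane=True`` adds 0.5 to both discordant sums before forming the
    statistic (off by default).  Boundary cases (NUM of 0 or DEN, or DEN of
    0) are flagged degenerate with NaN statistic and p.
    """
    rho, pi = _check_doses(rho, pi)
    num = float((rho * (1.0 - pi)).sum())
    other = float((pi * (1.0 - rho)).sum())
    if haldane:
        num += 0.5
        other += 0.5
    den = num + other
    if num <= 0.0 or other <= 0.0 or den <= 0.0:
        return PairedResult(num, den, np.nan, np.nan, np.nan, np.nan, True)
    beta = float(np.log(num / other))
    var_beta = den / (num * other)
    x = beta * beta / var_beta
    p = float(stats.chi2.sf(x, df=1))
    return PairedResult(num, den, beta, var_beta, x, p, False)


def unpaired_test(rho, pi) -> UnpairedResult:
    """Marginal-homogeneity test on the expected parental-allele 2x2 table.

    A = sum (1-rho)(1-pi), B = sum (1-rho) pi, C = sum rho (1-pi),
    D = sum rho pi; margins n1. = A + C, n2. = B + D, n.1 = A + B,
    n.2 = C + D; X = sum_m (n_m. - n._m)^2 / (n_m. + n._m).
    """
    rho, pi = _check_doses(rho, pi)
    a = float(((1.0 - rho) * (1.0 - pi)).sum())
    b = float(((1.0 - rho) * pi).sum())
    c = float((rho * (1.0 - pi)).sum())
    d = float((rho * pi).sum())
    n1_, n2_ = a + c, b + d
    n_1, n_2 = a + b, c + d
    s1, s2 = n1_ + n_1, n2_ + n_2
    if s1 <= 0.0 and s2 <= 0.0:
        return UnpairedResult(a, b, c, d, np.nan, np.nan, True)
    x = 0.0
    x += (n1_ - n_1) ** 2 / s1 if s1 > 0 else 0.0
    x += (n2_ - n_2) ** 2 / s2 if s2 > 0 else 0.0
    p = float(stats.chi2.sf(x, df=1))
    return UnpairedResult(a, b, c, d, x, p, False)


def inflation_lambda(x_stats) -> float:
    """Genomic inflation factor: median(X) / median(chi2_1)."""
    x = np.asarray(x_stats, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite statistics for lambda")
    return float(np.median(x) / CHI2_1_MEDIAN)


def genomic_control(
    records: pd.DataFrame,
    lam: float,
    columns: tuple[str, str] = ("x_paired", "p_paired"),
) -> pd.DataFrame:
    """Divide the chosen statistic by lambda and recompute p (no deflation).

    By convention lambda < 1 leaves the records untouched.
    """
    out = records.copy()
    if lam <= 1.0:
        return out
    x_col, p_col = columns
    x = out[x_col].to_numpy(dtype=float) / lam
    out[x_col] = x
    out[p_col] = np.where(np.isfinite(x), stats.chi2.sf(x, df=1), np.nan)
    return out


@dataclass(frozen=True)
class ScanConfig:
    """Scan-level options; thresholds default to the tool's standard 0.01/0.3."""

    maf_min: float = 0.01
    info_min: float = 0.3
    statistic: str = "paired"  # paired | unpaired | both; lambda uses paired unless unpaired-only
    gc: bool = False
    haldane: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 1.0 and 0.0 <= self.info_min <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.statistic not in ("paired", "unpaired", "both"):
            raise ValueError("statistic must be paired, unpaired or both")


@dataclass
class ScanSummary:
    lambda_gc: float
    n_sites: int
    n_tested: int
    n_filtered: int
    n_degenerate: int
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["lambda_gc"] = None if not np.isfinite(self.lambda_gc) else self.lambda_gc
        return json.dumps(d, indent=2)


def _scan_statistics(rho: np.ndarray, pi: np.ndarray, haldane: bool) -> dict[str, np.ndarray]:
    """Vectorized per-site NUM/DEN, A-D and both chi-square statistics."""
    num = (rho * (1.0 - pi)).sum(axis=0)
    other = (pi * (1.0 - rho)).sum(axis=0)
    if haldane:
        num = num + 0.5
        other = other + 0.5
    den = num + other
    ok = (num > 0) & (other > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, np.log(np.where(ok, num, 1.0) / np.where(ok, other, 1.0)), np.nan)
        var_beta = np.where(ok, den / (num * other), np.nan)
        x_paired = np.where(ok, beta * beta / var_beta, np.nan)
    a = ((1.0 - rho) * (1.0 - pi)).sum(axis=0)
    b = ((1.0 - rho) * pi).sum(axis=0)
    c = (rho * (1.0 - pi)).sum(axis=0)
    d = (rho * pi).sum(axis=0)
    s1 = 2.0 * a + b + c
    s2 = 2.0 * d + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        x_unpaired = np.where(s1 > 0, (c - b) ** 2 / np.where(s1 > 0, s1, 1.0), 0.0)
        x_unpaired = x_unpaired + np.where(
            s2 > 0, (b - c) ** 2 / np.where(s2 > 0, s2, 1.0), 0.0
        )
    x_unpaired = np.where((s1 <= 0) & (s2 <= 0), np.nan, x_unpaired)
    return {
        "num": num,
        "den": den,
        "beta": beta,
        "var_beta": var_beta,
        "x_paired": x_paired,
        "a": a,
        "b": b,
        "c": c,
        "d": d,
        "x_unpaired": x_unpaired,
    }


def scan_dosage_table(table: DosageTable, config: ScanConfig | None = None):
    """Apply filters and both tests to a prebuilt :class:`DosageTable`."""
    config = config or ScanConfig()
    maf = table.case_mafs()
    info = table.info_scores()
    filtered = np.full(len(maf), "", dtype=object)
    filtered[info < config.info_min] = "info"
    filtered[maf < config.maf_min] = "maf"  # maf takes precedence in the report
    keep = filtered == ""

    stats_d = _scan_statistics(table.rho, table.pi, config.haldane)
    records = table.sites[["chrom", "pos", "id", "ref", "alt"]].copy()
    records["typed"] = table.typed
    records["maf_case"] = maf
    records["info"] = info
    for k in ("num", "den", "beta", "var_beta", "a", "b", "c", "d"):
        records[k] = stats_d[k]
    records["se_beta"] = np.sqrt(stats_d["var_beta"])
    records["x_paired"] = stats_d["x_paired"]
    records["x_unpaired"] = stats_d["x_unpaired"]
    with np.errstate(invalid="ignore"):
        records["p_paired"] = np.where(
            np.isfinite(stats_d["x_paired"]), stats.chi2.sf(stats_d["x_paired"], df=1), np.nan
        )
        records["p_unpaired"] = np.where(
            np.isfinite(stats_d["x_unpaired"]),
            stats.chi2.sf(stats_d["x_unpaired"], df=1),
            np.nan,
        )
    # filtered records carry no statistics or p-values
    stat_cols = [
        "num", "den", "beta", "se_beta", "var_beta",
        "x_paired", "p_paired", "a", "b", "c", "d", "x_unpaired", "p_unpaired",
    ]
    records.loc[~keep, stat_cols] = np.nan
    records["filtered"] = ~keep
    records["filter_reason"] = filtered
    records["genome_wide"] = records["p_paired"] < GENOME_WIDE_P
    records["suggestive"] = records["p_paired"] < SUGGESTIVE_P

    lam_col = "x_unpaired" if config.statistic == "unpaired" else "x_paired"
    x_kept = records.loc[keep, lam_col].to_numpy(dtype=float)
    finite = np.isfinite(x_kept)
    lam = inflation_lambda(x_kept[finite]) if finite.any() else float("nan")
    n_degenerate = int(keep.sum() - finite.sum())
    if config.gc and np.isfinite(lam):
        records = genomic_control(records, lam, ("x_paired", "p_paired"))
        records = genomic_control(records, lam, ("x_unpaired", "p_unpaired"))
    summary = ScanSummary(
        lambda_gc=lam,
        n_sites=int(len(records)),
        n_tested=int(finite.sum()),
        n_filtered=int((~keep).sum()),
        n_degenerate=n_degenerate,
        config={
            "maf_min": config.maf_min,
            "info_min": config.info_min,
            "statistic": config.statistic,
            "gc": config.gc,
            "haldane": config.haldane,
        },
    )
    if not keep.any():
        logger.warning("scan: no sites survive the MAF/INFO filters")
    return records, summary


def run_surfbat(
    panel: HaplotypePanel,
    targets: TargetHaplotypes,
    params: HmmParams | None = None,
    config: ScanConfig | None = None,
):
    """End-to-end scan: copying HMM -> dosages -> per-site tests.

    Returns ``(records, summary, dosage_table)``; records is one row per
    panel site with the columns documented in the output TSV.
    """
    table = build_dosage_table(panel, targets, params)
    records, summary = scan_dosage_table(table, config)
    return records, summary, table
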