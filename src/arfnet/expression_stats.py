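"""qPCR and segregation statistics.

Relative fold change by the comparative-Ct method with a reference gene and
a calibrator line; Mann-Whitney significance of fold changes versus the
calibrator; and chi-square goodness-of-fit of antibiotic-resistance
segregation counts to Mendelian ratios.

The comparative-Ct model assumes amplification efficiency 2 (perfect
doubling per cycle): for each biological replicate
``dCt = Ct_target - Ct_reference``, ``ddCt = dCt - mean dCt(calibrator)``,
and the fold change is ``2**(-ddCt)``. Technical replicates are averaged
before any biological-replicate statistic. The reported point estimate is
``2**(-mean ddCt)`` — the geometric mean of per-replicate fold changes — so
the calibrator line is exactly 1 by construction; the standard error is
that of the per-replicate fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRecord",
    "RFCResult",
    "SegregationRecord",
    "delta_delta_ct",
    "mann_whitney",
    "chi_square_gof",
    "chi2_critical",
    "read_ct_table",
    "read_segregation_table",
]


@dataclass(frozen=True)
class CtRecord:
    line: str
    tissue: str
    gene: str
    bio_rep: str
    tech_rep: str
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"Ct must be positive, got {self.ct}")


@dataclass
class RFCResult:
    line: str
    tissue: str
    gene: str
    rfc: float
    se: float
    p: float
    n_bio: int
    n_tech: int
    significant: bool = False


@dataclass
class SegregationRecord:
    line: str
    resistant: int
    sensitive: int
    expected_ratio: tuple[int, int]
    chi2: float
    df: int = 1
    passed: bool = False


def read_ct_table(path) -> pd.DataFrame:
    """TSV with columns line, tissue, gene, bio_rep, tech_rep, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"bio_rep": str, "tech_rep": str})
    required = {"line", "tissue", "gene", "bio_rep", "tech_rep", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    return df


def _dct_per_bio_rep(
    df: pd.DataFrame, target_gene: str, reference_gene: str
) -> pd.DataFrame:
    """Mean over technical replicates, then dCt = target - reference."""
    means = (
        df[df["gene"].isin([target_gene, reference_gene])]
        .groupby(["line", "tissue", "gene", "bio_rep"], sort=True)["ct"]
        .mean()
        .unstack("gene")
    )
    for gene in (target_gene, reference_gene):
        if gene not in means.columns:
            raise ValueError(f"no Ct records for gene {gene!r}")
        bad = means[means[gene].isna()]
        if len(bad):
            line, tissue, rep = bad.index[0]
            raise ValueError(
                f"missing {gene!r} Ct for line={line!r} tissue={tissue!r} "
                f"bio_rep={rep!r}"
            )
    out = means.reset_index()
    out["dct"] = out[target_gene] - out[reference_gene]
    return out


def delta_delta_ct(
    records: pd.DataFrame | Sequence[CtRecord],
    target_gene: str,
    reference_gene: str,
    calibrator_line: str,
) -> list[RFCResult]:
    """Relative fold change of a target gene per (line, tissue).

    Significance is a two-sided Mann-Whitney test of the line's biological-
    replicate fold changes against the calibrator's, per tissue.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records])
    dct = _dct_per_bio_rep(records, target_gene, reference_gene)

    n_tech = int(
        records[records["gene"] == target_gene]
        .groupby(["line", "tissue", "bio_rep"])["tech_rep"]
        .nunique()
        .max()
    )

    results: list[RFCResult] = []
    for tissue, sub in dct.groupby("tissue", sort=True):
        cal = sub[sub["line"] == calibrator_line]
        if cal.empty:
            raise ValueError(
                f"missing reference data: calibrator {calibrator_line!r} has no "
                f"records for tissue {tissue!r}"
            )
        cal_mean = cal["dct"].mean()
        cal_rfc = np.power(2.0, -(cal["dct"].to_numpy() - cal_mean))
        for line, grp in sub.groupby("line", sort=True):
            ddct = grp["dct"].to_numpy() - cal_mean
            rfc_reps = np.power(2.0, -ddct)
            n_bio = len(rfc_reps)
            se = float(rfc_reps.std(ddof=1) / math.sqrt(n_bio)) if n_bio > 1 else 0.0
            if line == calibrator_line:
                p = 1.0
            else:
                _, p = mann_whitney(list(rfc_reps), list(cal_rfc))
            results.append(
                RFCResult(
                    line=line,
                    tissue=tissue,
                    gene=target_gene,
                    rfc=float(np.power(2.0, -ddct.mean())),
                    se=se,
                    p=float(p),
                    n_bio=n_bio,
                    n_tech=n_tech,
                    significant=bool(p < 0.05 and line != calibrator_line),
                )
            )
    return results


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midranks for ties.

    Exact p by enumeration of labelings when the pooled size is <= 12 with
    no ties; otherwise the normal approximation with tie and continuity
    corrections. Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = a.size + b.size <= 12
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_gof(
    resistant: int, sensitive: int, ratio: tuple[int, int], alpha: float = 0.05,
    line: str = "",
) -> SegregationRecord:
    """Uncorrected chi-square goodness of fit of counts to an a:b ratio.

    No continuity correction is applied. ``passed`` is true when the
    statistic does not exceed the upper-alpha critical value at 1 df.
    """
    if resistant < 0 or sensitive < 0:
        raise ValueError("counts must be non-negative")
    total = resistant + sensitive
    if total == 0:
        raise ValueError("total count must be positive")
    va, vb = ratio
    if va <= 0 and vb <= 0:
        raise ValueError("expected ratio must have a positive component")
    exp_r = total * va / (va + vb)
    exp_s = total * vb / (va + vb)
    chi2 = 0.0
    for obs, exp in ((resistant, exp_r), (sensitive, exp_s)):
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
        elif obs > 0:
            raise ValueError("observed count in a category with zero expectation")
    crit = chi2_critical(alpha, 1)
    return SegregationRecord(
        line=line,
        resistant=resistant,
        sensitive=sensitive,
        expected_ratio=ratio,
        chi2=float(chi2),
        df=1,
        passed=bool(chi2 <= crit),
    )


def chi2_critical(alpha: float = 0.05, df: int = 1) -> float:
    """Upper-alpha quantile of the chi-square distribution."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def read_segregation_table(path) -> pd.DataFrame:
    """TSV with columns line, resistant, sensitive, ratio (formatted 'a:b')."""
    df = pd.read_csv(path, sep="\t")
    required = {"line", "resistant", "sensitive", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segregation table missing columns {sorted(missing)}")
    return df


def segregation_report(df: pd.DataFrame, alpha: float = 0.05) -> list[SegregationRecord]:
    records = []
    for row in df.itertuples():
        a, b = (int(x) for x in str(row.ratio).split(":"))
        records.append(
            chi_square_gof(int(row.resistant), int(row.sensitive), (a, b), alpha, line=row.line)
        )
    return records
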