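"""Internal-consistency ICC (Cronbach's alpha) for repeated volume
measurements.

The statistic is alpha = N*cbar / (vbar + (N-1)*cbar), where N is the
number of rater columns (sessions, platforms or algorithm versions),
cbar the mean off-diagonal entry of the between-rater covariance matrix
computed over subjects, and vbar the mean diagonal entry.  This equals
the average-measures consistency ICC of a two-way mixed model, ICC(3,k):
a systematic per-rater offset does not reduce it.  Confidence intervals
use Feldt's F-distribution argument, the classical interval for alpha.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    InsufficientDataError,
    MeasurementTable,
    ReliabilityResult,
    UndefinedResultError,
)
from .refdata import V6_TO_V53_PAIRING


def cronbach_alpha(table: MeasurementTable) -> float:
    """Cronbach's alpha over the rater columns of a measurement table.

    Uses the unbiased covariance estimator (divisor n-1).  Alpha is at
    most 1 by construction and is not clipped from below; strongly
    discordant raters can give negative values.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 raters or 3 subjects.
    UndefinedResultError
        Zero total variance (all measurements identical).
    """
    x = table.values
    n, k = x.shape
    if k < 2:
        raise InsufficientDataError("alpha needs at least 2 rater columns")
    if n < 3:
        raise InsufficientDataError("alpha needs at least 3 subjects")
    cov = np.cov(x, rowvar=False, ddof=1)
    vbar = float(np.mean(np.diag(cov)))
    off = cov[~np.eye(k, dtype=bool)]
    cbar = float(np.mean(off))
    denom = vbar + (k - 1) * cbar
    if denom <= 0:
        if np.allclose(cov, 0):
            raise UndefinedResultError(
                "all measurements are identical; alpha is undefined"
            )
        raise UndefinedResultError("non-positive total variance; alpha undefined")
    return k * cbar / denom


def alpha_confidence_interval(
    alpha: float, n_subjects: int, n_raters: int, level: float = 0.95
) -> tuple[float, float]:
    """Feldt confidence interval for Cronbach's alpha.

    (1 - alpha-hat)/(1 - alpha) follows an F distribution with
    (n-1, (n-1)(k-1)) degrees of freedom; inverting gives

        bound(q) = 1 - (1 - alpha-hat) * F_q(n-1, (n-1)(k-1))

    evaluated at q = 1 - level/2 (lower) and q = level/2 (upper).

    Returns (1.0, 1.0) with a warning-free degenerate interval when
    alpha == 1 (no residual variance to bound).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_subjects < 3:
        raise InsufficientDataError("need at least 3 subjects for an interval")
    if alpha >= 1.0:
        return (1.0, 1.0)
    df1 = n_subjects - 1
    df2 = (n_subjects - 1) * (n_raters - 1)
    tail = (1.0 - level) / 2.0
    f_hi = stats.f.ppf(1.0 - tail, df1, df2)
    f_lo = stats.f.ppf(tail, df1, df2)
    lower = 1.0 - (1.0 - alpha) * f_hi
    upper = 1.0 - (1.0 - alpha) * f_lo
    return (float(lower), float(upper))


def reliability_result(
    table: MeasurementTable, level: float = 0.95
) -> ReliabilityResult:
    """Alpha with its Feldt interval, packaged per region."""
    a = cronbach_alpha(table)
    lo, hi = alpha_confidence_interval(a, table.n_subjects, table.n_raters, level)
    return ReliabilityResult(
        region=table.region_name,
        icc=float(a),
        ci_lower=lo,
        ci_upper=hi,
        n_subjects=table.n_subjects,
        n_raters=table.n_raters,
    )


def cross_version_icc_matrix(
    volumes_v6: pd.DataFrame,
    volumes_v53: pd.DataFrame,
    pairing: Mapping[str, Sequence[str]] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Between-version agreement ICC matrix.

    Parameters
    ----------
    volumes_v6, volumes_v53 : DataFrame
        Subjects x regions frames of bilaterally averaged volumes in
        mm^3 (v5.3 volumes already rescaled from 0.5-mm voxel units),
        indexed by subject id.
    pairing : mapping, optional
        v6.0 region -> v5.3 regions to compare against.  Defaults to
        the shipped harmonization map, which cross-pairs the
        cornu-ammonis sectors and leaves v6.0-only regions unpaired.

    Returns
    -------
    DataFrame
        Rows = v6.0 regions, columns = v5.3 regions; entries are the
        two-column Cronbach's alpha, NaN for unpaired cells.
    """
    if pairing is None:
        pairing = {
            k: v for k, v in V6_TO_V53_PAIRING.items()
            if k in volumes_v6.columns
        }
    shared = volumes_v6.index.intersection(volumes_v53.index)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} subjects shared between the two versions"
        )
    v53_cols = sorted({c for cols in pairing.values() for c in cols},
                      key=list(volumes_v53.columns).index)
    out = pd.DataFrame(np.nan, index=list(pairing), columns=v53_cols)
    for region6, partners in pairing.items():
        for region53 in partners:
            tbl = MeasurementTable(
                region_name=f"{region6}~{region53}",
                rater_labels=["v6.0", "v5.3"],
                values=np.column_stack(
                    [
                        volumes_v6.loc[shared, region6].to_numpy(float),
                        volumes_v53.loc[shared, region53].to_numpy(float),
                    ]
                ),
                subject_ids=[str(s) for s in shared],
            )
            out.loc[region6, region53] = cronbach_alpha(tbl)
    return out


def median_icc(values: Sequence[float] | Sequence[ReliabilityResult]) -> float:
    """Sample median of a collection of ICCs (mean of the two central
    values for even counts)."""
    vals = [v.icc if isinstance(v, ReliabilityResult) else float(v) for v in values]
    if len(vals) == 0:
        raise InsufficientDataError("median of an empty ICC list")
    return float(np.median(vals))
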