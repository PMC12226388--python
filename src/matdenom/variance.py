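"""Delete-one-cluster jackknife standard errors for survey statistics.

Household surveys sample clusters (primary sampling units) within strata, so
observations are not independent and naive variance formulas understate
uncertainty. The jackknife deletes one cluster at a time — within its
stratum, keeping every other stratum intact — recomputes the statistic, and
combines the replicates through pseudo-values:

    r_i* = k r - (k - 1) r_(i)
    SE   = sqrt( sum_i (r_i* - rbar*)^2 / (k (k - 1)) )

with k the total number of clusters, r the full-sample statistic, r_(i) the
statistic without cluster i, and rbar* the mean pseudo-value. Confidence
intervals use the normal approximation (z = 1.96 for 95%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ReplicateFailureError
from .data_model import Survey

__all__ = ["JackknifeResult", "jackknife", "jackknife_from_replicates", "Z_95"]

Z_95 = 1.96


@dataclass
class JackknifeResult:
    """Point estimate with jackknife SE and normal-approximation CI.

    ``ci_low`` is stored untruncated (it may be negative for a small
    non-negative statistic); reporting layers clip at zero for display.
    ``replicate_values`` holds the delete-one-cluster statistics r_(i).
    """

    point: float
    se: float
    ci_low: float
    ci_high: float
    n_clusters: int
    replicate_values: list[float] = field(default_factory=list)
    n_dropped_replicates: int = 0


def jackknife_from_replicates(
    point: float,
    replicate_values,
    z: float = Z_95,
    n_dropped: int = 0,
) -> JackknifeResult:
    """Combine a full-sample statistic and its delete-one-cluster replicates."""
    r = np.asarray(replicate_values, dtype=float)
    k = r.size
    if k < 2:
        raise ReplicateFailureError(f"need at least 2 usable clusters, got {k}")
    pseudo = k * point - (k - 1) * r
    se = float(np.sqrt(np.sum((pseudo - pseudo.mean()) ** 2) / (k * (k - 1))))
    return JackknifeResult(
        point=float(point),
        se=se,
        ci_low=float(point - z * se),
        ci_high=float(point + z * se),
        n_clusters=k,
        replicate_values=[float(v) for v in r],
        n_dropped_replicates=n_dropped,
    )


def jackknife(
    statistic,
    survey: Survey,
    z: float = Z_95,
    drop_failing_replicates: bool = False,
) -> JackknifeResult:
    """Jackknife a scalar survey statistic over delete-one-cluster subsamples.

    ``statistic`` is any callable Survey -> float. Clusters are deleted one
    at a time within their stratum (all other strata untouched). If the
    statistic fails on some subsample (e.g. a cluster holds every death),
    the default is to raise :class:`ReplicateFailureError` listing the
    clusters; with ``drop_failing_replicates=True`` failing replicates are
    omitted and counted in the result instead.
    """
    keys = survey.cluster_keys()
    k = len(keys)
    if k < 2:
        raise ReplicateFailureError(f"survey has {k} cluster(s); jackknife needs >= 2")
    point = float(statistic(survey))
    replicates: list[float] = []
    failures: list[tuple[str, str]] = []
    for stratum, cluster in keys.itertuples(index=False):
        sub = survey.drop_cluster(stratum, cluster)
        try:
            replicates.append(float(statistic(sub)))
        except Exception:
            failures.append((stratum, cluster))
    if failures and not drop_failing_replicates:
        raise ReplicateFailureError(
            f"statistic failed on {len(failures)} delete-one-cluster subsample(s): "
            f"{failures[:10]}"
        )
    return jackknife_from_replicates(point, replicates, z=z, n_dropped=len(failures))
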