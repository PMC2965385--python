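"""Per-gene condition profiles, significance flagging and sample QC.

Replicates are collapsed to medians (with the SEM as a dispersion
estimate), mirroring how replicate array profiles are usually displayed.
Significant changes between two conditions are called with a one-sided
Welch t-test on the replicate log2 values followed by Benjamini-Hochberg
adjustment and a minimum-effect filter; all three knobs are exposed.
Sample-level QC clusters array columns by complete linkage on the
1 - Pearson correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .matrix import CONDITIONS, ExpressionMatrix, condition_label

DIRECTIONS = ("less", "greater")


def summarize_replicates(
    matrix: ExpressionMatrix, detection_threshold: float
) -> pd.DataFrame:
    """Median, SEM and detection status per gene and condition.

    Returns a gene-indexed frame with ``median_<cond>``, ``sem_<cond>``
    and ``detected_<cond>`` columns for each of U1..E3.  A condition
    measured by a single replicate gets SEM 0 by convention; a gene is
    detected when its median exceeds ``detection_threshold``.
    """
    out: dict[str, pd.Series] = {}
    for series, tp in CONDITIONS:
        cond = condition_label(series, tp)
        vals = matrix.condition_values(series, tp)
        if vals.shape[1] == 0:
            raise ValueError(f"condition {cond} has zero samples")
        med = vals.median(axis=1)
        if vals.shape[1] > 1:
            sem = vals.std(axis=1, ddof=1) / np.sqrt(vals.shape[1])
        else:
            sem = pd.Series(0.0, index=vals.index)
        out[f"median_{cond}"] = med
        out[f"sem_{cond}"] = sem
        out[f"detected_{cond}"] = med > detection_threshold
    profiles = pd.DataFrame(out)
    profiles.index.name = "gene_id"
    return profiles


def _welch_one_sided(
    xa: np.ndarray, xb: np.ndarray, direction: str
) -> np.ndarray:
    """Vectorized one-sided Welch t-test p-values, rows are genes.

    Zero-variance rows (exact replicates, e.g. noise-free simulations)
    are resolved by the sign of the mean difference so that noiseless
    data still yield the obvious call.
    """
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("both conditions need >= 2 replicates for testing")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        if direction == "less":
            p = stats.t.cdf(t, df)
        else:
            p = stats.t.sf(t, df)
    degenerate = se2 == 0
    if degenerate.any():
        signed = diff[degenerate]
        if direction == "less":
            p[degenerate] = np.where(signed < 0, 0.0, 1.0)
        else:
            p[degenerate] = np.where(signed > 0, 0.0, 1.0)
    return np.clip(p, 0.0, 1.0)


def flag_significant_change(
    matrix: ExpressionMatrix,
    condition: tuple[str, int],
    reference: tuple[str, int],
    direction: str = "less",
    fdr: float = 0.10,
    min_effect: float = 0.5,
) -> pd.DataFrame:
    """Call genes changing between two conditions in a stated direction.

    ``direction='less'`` tests condition < reference.  The reported
    effect is the difference of replicate medians (condition minus
    reference, log2 units); a gene is flagged when its BH-adjusted q is
    at or below ``fdr`` and the effect exceeds ``min_effect`` in the
    tested direction.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    from .enrichment import bh_adjust  # local import to avoid a cycle

    xa = matrix.condition_values(*condition).to_numpy(float)
    xb = matrix.condition_values(*reference).to_numpy(float)
    effect = np.median(xa, axis=1) - np.median(xb, axis=1)
    p = _welch_one_sided(xa, xb, direction)
    q, reject = bh_adjust(p, fdr=fdr)
    if direction == "less":
        effect_ok = effect <= -min_effect
    else:
        effect_ok = effect >= min_effect
    return pd.DataFrame(
        {
            "effect": effect,
            "p": p,
            "q": q,
            "flag": reject & effect_ok,
        },
        index=matrix.gene_ids,
    )


@dataclass
class SampleClustering:
    linkage_matrix: np.ndarray
    labels: pd.Series  # flat cluster id per sample at the requested k
    excluded: list[str]  # zero-variance samples dropped from clustering


def sample_distances(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson r distance between sample columns."""
    d = squareform(pdist(values.to_numpy(float).T, metric="correlation"))
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def cluster_samples(matrix: ExpressionMatrix, k: int = 6) -> SampleClustering:
    """Complete-linkage clustering of samples on correlation distance.

    Expression is first median-centered per gene (each sample is
    compared as deviation from the gene's median across all samples, the
    way replicate-group QC heatmaps are drawn); without centering the
    shared gene-level expression structure dominates every pairwise
    correlation.  Samples with zero variance (correlation undefined) are
    excluded with a warning.  On a well-behaved 6-condition x
    n-replicate design, cutting at k=6 recovers the replicate groups.
    """
    raw = matrix.values
    excluded = list(raw.columns[raw.std(axis=0, ddof=0) == 0])
    if excluded:
        warnings.warn(
            f"excluding zero-variance samples from clustering: {excluded}",
            stacklevel=2,
        )
        raw = raw.drop(columns=excluded)
    values = raw.sub(raw.median(axis=1), axis=0)
    if values.shape[1] < 2:
        raise ValueError("need at least two non-degenerate samples to cluster")
    d = pdist(values.to_numpy(float).T, metric="correlation")
    z = linkage(d, method="complete")
    flat = fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=values.columns, name="cluster")
    return SampleClustering(linkage_matrix=z, labels=labels, excluded=excluded)


def replicate_groups_recovered(
    matrix: ExpressionMatrix,
    clustering: SampleClustering,
    group_of: dict[tuple[str, int], str] | None = None,
) -> bool:
    """True when flat clusters coincide exactly with condition groups.

    ``group_of`` maps (series, timepoint) to a group label; by default
    every condition is its own group.  Conditions that are identical by
    design (e.g. embryos and eggs sampled before the zygotic onset) can
    be merged into one group via this mapping.
    """
    design = matrix.design.loc[clustering.labels.index]
    if group_of is None:
        truth = design["series"].astype(str) + design["timepoint"].astype(str)
    else:
        truth = design.apply(
            lambda r: group_of[(r["series"], int(r["timepoint"]))], axis=1
        )
    table = pd.crosstab(truth, clustering.labels)
    return bool(((table > 0).sum(axis=0) == 1).all() and ((table > 0).sum(axis=1) == 1).all())


def default_detection_threshold(matrix: ExpressionMatrix) -> float:
    """Fallback presence threshold: 5th percentile of U1 medians."""
    u1 = matrix.condition_values("U", 1).median(axis=1)
    return float(np.percentile(u1, 5))
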