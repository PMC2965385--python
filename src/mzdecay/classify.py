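"""Nine-way transcript stability classification.

Each gene's call is derived from a small set of evidence flags computed
on the paired egg/embryo series:

* ``preloaded``          - detected at U1 (maternal provision present)
* ``maternal_decay``     - U3 significantly below U1
* ``zygotic_decay``      - E3 significantly below U3
* ``transcription``      - E3 significantly above U3
* ``transcription_mid``  - E2 significantly above U2

The unfertilized-egg series isolates the maternal decay machinery;
embryo-versus-egg divergence at matched times reports the *net* effect
of zygotic transcription and zygotic decay (the two are not
deconvolved - only the dominant effect is visible).  The decision table:

=========  ========  =======  ============  ==============  =====================
preloaded  maternal  zygotic  transcription trans. at E2    class
=========  ========  =======  ============  ==============  =====================
yes        -         yes      -             yes             NOT_CLASSIFIED (rise/fall)
yes        no        no       no            no              I   (stable)
yes        yes       no       no            -               II  (maternal decay)
yes        yes       no       yes           -               III (maternal decay + txn)
yes        no        yes      no            no              IV  (zygotic decay)
yes        yes       yes      no            no              V   (mixed decay)
yes        no        no       yes           -               STABLE_TRANSCRIPTION
yes        (other combinations)                             NOT_CLASSIFIED
no         -         -        yes (any)     -               PURELY_ZYGOTIC
no         -         -        no            no              NOT_EXPRESSED
=========  ========  =======  ============  ==============  =====================

``zygotic_decay`` and ``transcription`` come from opposite one-sided
tests on the same contrast and cannot both be significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matrix import ExpressionMatrix
from .profiles import flag_significant_change, summarize_replicates, default_detection_threshold
from .simulate import (
    CLASS_I,
    CLASS_II,
    CLASS_III,
    CLASS_IV,
    CLASS_V,
    CLASS_LABELS,
    NOT_CLASSIFIED,
    NOT_EXPRESSED,
    PURELY_ZYGOTIC,
    STABLE_TRANSCRIPTION,
)

#: classes counted against the preloaded (maternally provided) total
PRELOADED_CLASSES = (
    CLASS_I,
    CLASS_II,
    CLASS_III,
    CLASS_IV,
    CLASS_V,
    STABLE_TRANSCRIPTION,
    NOT_CLASSIFIED,
)

DECAY_SUPERCLASS = (CLASS_II, CLASS_III, CLASS_IV, CLASS_V)

EVIDENCE_FIELDS = (
    "preloaded",
    "maternal_decay",
    "zygotic_decay",
    "transcription",
    "transcription_mid",
)


@dataclass
class ClassifyConfig:
    fdr: float = 0.10
    min_effect: float = 0.5
    detection_threshold: float | None = None  # None -> 5th percentile of U1 medians


def assign_class(evidence: dict) -> str:
    """Map one gene's evidence flags to a stability class label."""
    missing = [f for f in EVIDENCE_FIELDS if f not in evidence]
    if missing:
        raise ValueError(f"missing evidence fields: {missing}")
    pre = bool(evidence["preloaded"])
    m = bool(evidence["maternal_decay"])
    z = bool(evidence["zygotic_decay"])
    t = bool(evidence["transcription"])
    t_mid = bool(evidence["transcription_mid"])

    if not pre:
        return PURELY_ZYGOTIC if (t or t_mid) else NOT_EXPRESSED
    if z and t_mid:
        # embryo signal rose above eggs at t2 then fell below at t3:
        # a complex pattern the five-class scheme cannot represent
        return NOT_CLASSIFIED
    if m and t:
        return CLASS_III
    if m and z:
        return CLASS_V
    if m:
        return CLASS_II
    if z:
        return CLASS_IV
    if t:
        return STABLE_TRANSCRIPTION
    if t_mid:
        return NOT_CLASSIFIED  # transient rise at t2 only
    return CLASS_I


def compute_evidence(
    matrix: ExpressionMatrix, config: ClassifyConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evidence flags (+ q-values) and the profile table for a matrix."""
    config = config or ClassifyConfig()
    threshold = config.detection_threshold
    if threshold is None:
        threshold = default_detection_threshold(matrix)
    profiles = summarize_replicates(matrix, detection_threshold=threshold)

    contrasts = {
        "maternal_decay": (("U", 3), ("U", 1), "less"),
        "zygotic_decay": (("E", 3), ("U", 3), "less"),
        "transcription": (("E", 3), ("U", 3), "greater"),
        "transcription_mid": (("E", 2), ("U", 2), "greater"),
    }
    evidence = pd.DataFrame(index=matrix.gene_ids)
    evidence["preloaded"] = profiles["detected_U1"]
    for name, (cond, ref, direction) in contrasts.items():
        table = flag_significant_change(
            matrix, cond, ref, direction=direction,
            fdr=config.fdr, min_effect=config.min_effect,
        )
        evidence[name] = table["flag"]
        evidence[f"q_{name}"] = table["q"]
        evidence[f"effect_{name}"] = table["effect"]
    return evidence, profiles


def classify_dataset(
    matrix: ExpressionMatrix, config: ClassifyConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every gene and summarize class proportions.

    Returns ``(calls, summary)``: calls carry the label plus all evidence
    flags and q-values; the summary reports counts and percentages of the
    preloaded total (one decimal) for each class and for the decay
    superclass II-V.
    """
    evidence, profiles = compute_evidence(matrix, config)
    labels = [
        assign_class(row) for row in evidence[list(EVIDENCE_FIELDS)].to_dict("records")
    ]
    calls = evidence.copy()
    calls.insert(0, "class_label", labels)
    return calls, class_summary(calls)


def percent_of(count: int, total: int) -> float:
    """Class percentage as printed in summaries: 100*count/total, one decimal."""
    if total == 0:
        return float("nan")
    return round(100.0 * count / total, 1)


def class_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and percent-of-preloaded per class, plus the II-V superclass."""
    label_counts = calls["class_label"].value_counts()
    n_preloaded = int(sum(label_counts.get(c, 0) for c in PRELOADED_CLASSES))
    rows = []
    for label in CLASS_LABELS:
        n = int(label_counts.get(label, 0))
        pct = percent_of(n, n_preloaded) if label in PRELOADED_CLASSES else float("nan")
        rows.append({"class_label": label, "count": n, "pct_of_preloaded": pct})
    n_decay = int(sum(label_counts.get(c, 0) for c in DECAY_SUPERCLASS))
    rows.append(
        {
            "class_label": "II-V",
            "count": n_decay,
            "pct_of_preloaded": percent_of(n_decay, n_preloaded),
        }
    )
    summary = pd.DataFrame(rows)
    summary.attrs["n_preloaded"] = n_preloaded
    return summary


def classification_accuracy(calls: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of genes whose call matches the simulator's class label."""
    merged = truth.set_index("gene_id")["class_label"].reindex(calls.index)
    return float((calls["class_label"] == merged).mean())
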