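"""Ground-truth simulator for paired embryo / unfertilized-egg time courses.

The generative model mirrors the mass-balance view of early-embryo mRNA
pools.  For a transcript with maternal provision ``X_M`` (log2 units), the
unfertilized-egg series only ever sees maternal decay,

    log2 X_U(t) = X_M - k_m * max(0, t - t_m) * log2(e),

while the embryo series additionally gains zygotically transcribed copies
and loses copies to the zygotic decay machinery once embryonic
transcription has started,

    X_E(t) = [2^{X_M - k_m dt_m log2 e} + 2^{X_M} (2^{g dt_txn / 60} - 1)]
             * 2^{-k_z dt_z log2 e}.

Decay rates ``k_m``/``k_z`` are per-minute first-order constants, so decay
is additive on the log2 scale; transcription is additive in concentration
(a pure-transcription gene rises exactly ``g`` log2 units per hour).
Replicate noise is i.i.d. Gaussian on the log2 scale, emulating
variance-stabilized array data.

Nine ground-truth stability classes are generated: the five major classes
(I stable, II exclusively maternal decay, III maternal decay with
transcription, IV exclusively zygotic decay, V mixed decay), purely
zygotic and stable+transcription genes, complex/non-classifiable patterns
(an early transcription burst erased by strong zygotic decay) and
non-expressed genes sitting at the detection floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, CONDITIONS, condition_label

LOG2E = math.log2(math.e)

CLASS_I = "I"
CLASS_II = "II"
CLASS_III = "III"
CLASS_IV = "IV"
CLASS_V = "V"
PURELY_ZYGOTIC = "PURELY_ZYGOTIC"
STABLE_TRANSCRIPTION = "STABLE_TRANSCRIPTION"
NOT_CLASSIFIED = "NOT_CLASSIFIED"
NOT_EXPRESSED = "NOT_EXPRESSED"

CLASS_LABELS = (
    CLASS_I,
    CLASS_II,
    CLASS_III,
    CLASS_IV,
    CLASS_V,
    PURELY_ZYGOTIC,
    STABLE_TRANSCRIPTION,
    NOT_CLASSIFIED,
    NOT_EXPRESSED,
)

TRUTH_COLUMNS = [
    "gene_id",
    "class_label",
    "maternal_level_log2",
    "maternal_rate",
    "zygotic_rate",
    "transcription_gain_log2_per_hr",
    "maternal_onset_min",
    "zygotic_onset_min",
    "transcription_onset_min",
    "true_half_life_min",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    ``n_genes_per_class`` may be a single count (applied to all nine
    classes) or a mapping from class label to count; classes absent from
    the mapping are not generated.  Sampling times default to the
    midpoints of the 30-minute collection windows (30-60, 90-120 and
    150-180 minutes after egg laying), so consecutive time points are 60
    minutes apart.  Zygotic transcription and decay switch on at
    ``zygotic_onset_min`` (default 110 min, after the second sampling
    point); maternal decay starts at egg activation (0 min).
    """

    n_genes_per_class: int | dict[str, int] = 100
    noise_sd: float = 0.2
    n_replicates: int = 4
    time_grid_min: tuple[float, float, float] = (45.0, 105.0, 165.0)
    zygotic_onset_min: float = 110.0
    maternal_onset_min: float = 0.0
    seed: int = 0
    detection_floor_log2: float = 4.0
    # ranges the per-gene effect sizes are drawn from (log2 units)
    maternal_level_range: tuple[float, float] = (8.0, 12.0)
    maternal_drop_range: tuple[float, float] = (1.0, 3.0)
    zygotic_drop_range: tuple[float, float] = (1.0, 2.5)
    transcription_gain_range: tuple[float, float] = (1.2, 2.5)

    def class_counts(self) -> dict[str, int]:
        if isinstance(self.n_genes_per_class, dict):
            counts = dict(self.n_genes_per_class)
        else:
            counts = {label: int(self.n_genes_per_class) for label in CLASS_LABELS}
        unknown = sorted(set(counts) - set(CLASS_LABELS))
        if unknown:
            raise ValueError(f"unknown class labels in config: {unknown}")
        for label, n in counts.items():
            if n <= 0:
                raise ValueError(f"non-positive gene count for class {label}: {n}")
        return counts

    def validate(self) -> None:
        self.class_counts()
        grid = tuple(self.time_grid_min)
        if len(grid) != 3 or not (grid[0] < grid[1] < grid[2]):
            raise ValueError(f"time grid must be three strictly increasing times, got {grid}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def make_truth(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-gene generative parameters for every configured class."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t1, t2, t3 = config.time_grid_min
    span_u = t3 - t1  # maternal decay window visible in the U series
    span_z = t3 - config.zygotic_onset_min  # zygotic window visible at t3
    if span_z <= 0:
        raise ValueError("zygotic onset must precede the last sampling time")

    rows: list[dict] = []
    idx = 0
    for label, n in config.class_counts().items():
        level = rng.uniform(*config.maternal_level_range, size=n)
        km = np.zeros(n)
        kz = np.zeros(n)
        gain = np.zeros(n)
        txn_onset = np.full(n, config.zygotic_onset_min)
        if label in (CLASS_II, CLASS_III, CLASS_V):
            # maternal rate set so the U1->U3 log2 drop lands in the configured range
            km = rng.uniform(*config.maternal_drop_range, size=n) / (span_u * LOG2E)
        if label in (CLASS_IV, CLASS_V):
            # zygotic rate set so the post-onset log2 drop at t3 lands in range
            kz = rng.uniform(*config.zygotic_drop_range, size=n) / (span_z * LOG2E)
        if label in (CLASS_III, STABLE_TRANSCRIPTION, PURELY_ZYGOTIC):
            gain = rng.uniform(*config.transcription_gain_range, size=n)
        if label in (PURELY_ZYGOTIC, NOT_EXPRESSED):
            level = np.full(n, config.detection_floor_log2)
        if label == NOT_CLASSIFIED:
            # complex pattern: early transcription burst, then zygotic decay
            # strong enough to pull E3 below U3 (rise-then-fall in embryos)
            gain = rng.uniform(1.2, 1.8, size=n)
            txn_onset = np.full(n, 50.0)
            excess = rng.uniform(1.0, 2.0, size=n)
            kz = (gain * (t3 - 50.0) / 60.0 + excess) / (span_z * LOG2E)

        total_rate = km + kz
        with np.errstate(divide="ignore"):
            half_life = np.where(total_rate > 0, math.log(2) / np.where(total_rate > 0, total_rate, 1.0), np.inf)
        for j in range(n):
            rows.append(
                {
                    "gene_id": f"sim{idx:05d}",
                    "class_label": label,
                    "maternal_level_log2": level[j],
                    "maternal_rate": km[j],
                    "zygotic_rate": kz[j],
                    "transcription_gain_log2_per_hr": gain[j],
                    "maternal_onset_min": config.maternal_onset_min,
                    "zygotic_onset_min": config.zygotic_onset_min,
                    "transcription_onset_min": txn_onset[j],
                    "true_half_life_min": half_life[j],
                }
            )
            idx += 1
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def signal_log2(truth: pd.DataFrame, series: str, t_min: float) -> np.ndarray:
    """Noise-free log2 expression of every truth gene at time ``t_min``."""
    level = truth["maternal_level_log2"].to_numpy(float)
    km = truth["maternal_rate"].to_numpy(float)
    dt_m = np.maximum(0.0, t_min - truth["maternal_onset_min"].to_numpy(float))
    log2_maternal = level - km * dt_m * LOG2E
    if series == "U":
        return log2_maternal
    if series != "E":
        raise ValueError(f"unknown series {series!r}")
    kz = truth["zygotic_rate"].to_numpy(float)
    gain = truth["transcription_gain_log2_per_hr"].to_numpy(float)
    dt_z = np.maximum(0.0, t_min - truth["zygotic_onset_min"].to_numpy(float))
    dt_txn = np.maximum(0.0, t_min - truth["transcription_onset_min"].to_numpy(float))
    linear = 2.0 ** log2_maternal + 2.0 ** level * (2.0 ** (gain * dt_txn / 60.0) - 1.0)
    return np.log2(linear) - kz * dt_z * LOG2E


def simulate_from_truth(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Render a replicate expression matrix from a truth table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    columns: list[str] = []
    design_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    times = dict(zip((1, 2, 3), config.time_grid_min))
    for series, tp in CONDITIONS:
        clean = signal_log2(truth, series, times[tp])
        for rep in range(1, config.n_replicates + 1):
            sample = f"{condition_label(series, tp)}_rep{rep}"
            columns.append(sample)
            design_rows.append(
                {"sample": sample, "series": series, "timepoint": tp, "replicate": rep}
            )
            noise = rng.normal(0.0, config.noise_sd, size=len(truth)) if config.noise_sd > 0 else 0.0
            blocks.append(clean + noise)
    values = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(truth["gene_id"], name="gene_id"), columns=columns
    )
    design = pd.DataFrame(design_rows).set_index("sample")
    return ExpressionMatrix(values, design)


def simulate_dataset(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate one paired U/E time-course matrix plus its truth table.

    Rows of the matrix and rows of the truth table are aligned 1:1.
    Reproducible: the same config (including seed) yields bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = make_truth(config, rng)
    matrix = simulate_from_truth(truth, config, rng)
    return matrix, truth


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a parsed YAML/JSON mapping."""
    known = {f.name for f in SimConfig.__dataclass_fields__.values()}
    unknown = sorted(set(d) - known)
    if unknown:
        raise ValueError(f"unknown simulation config keys: {unknown}")
    kwargs = dict(d)
    for key in ("time_grid_min", "maternal_level_range", "maternal_drop_range",
                "zygotic_drop_range", "transcription_gain_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return SimConfig(**kwargs)


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    for key, value in d.items():
        if isinstance(value, tuple):
            d[key] = list(value)
    return d
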