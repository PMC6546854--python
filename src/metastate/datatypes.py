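"""Core containers shared across the pipeline.

The study design this package models is a paired (within-subject) two-condition
resting-state fMRI experiment: each subject is scanned once hungry and once
satiated, features are extracted voxel-wise, averaged over an anatomical
parcellation, and the resulting samples x regions table is classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

HUNGER = "hunger"
SATIETY = "satiety"
CONDITIONS = (HUNGER, SATIETY)

FEATURE_KINDS = ("reho", "dc", "falff")


def default_region_table() -> list[tuple[int, str]]:
    """The 90-region AAL parcellation table (cerebellum excluded), in the
    fixed label order used for region vectors R[1..90]."""
    with resources.files("metastate.data").joinpath("aal90_regions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return list(zip(df["label"].astype(int), df["name"].astype(str)))


@dataclass(frozen=True)
class CohortSpec:
    """Study design of a two-condition paired rs-fMRI cohort."""

    n_subjects: int = 24
    n_timepoints: int = 170
    tr: float = 2.0
    conditions: tuple[str, str] = CONDITIONS

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_timepoints < 16:
            raise ValueError("n_timepoints must be >= 16")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ValueError("exactly two distinct conditions are required")

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth condition effect injected by the synthetic generator.

    ``effect_kind`` names the feature the effect size refers to: ``amplitude``
    modulates the latent low-frequency signal's amplitude (targets fALFF),
    ``local_coherence`` modulates the voxel-to-latent coupling (targets ReHo),
    ``global_coupling`` modulates the weight of a brain-wide shared component
    (targets DC).  ``effect_size`` is the standardized mean difference
    (Cohen's d) of the targeted region-mean feature between conditions.
    """

    informative_regions: frozenset[int] = frozenset()
    effect_kind: str = "amplitude"
    effect_size: float = 0.0
    subject_rho: float = 0.5
    noise_sd: float = 1.0
    coupling: float | Mapping[int, float] = 1.0
    global_weight: float = 0.5
    n_sinusoids: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "informative_regions", frozenset(int(r) for r in self.informative_regions))
        if self.effect_kind not in ("amplitude", "local_coherence", "global_coupling"):
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if not (0.0 <= self.subject_rho < 1.0):
            raise ValueError("subject_rho must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def coupling_for(self, label: int) -> float:
        if isinstance(self.coupling, Mapping):
            return float(self.coupling.get(label, 1.0))
        return float(self.coupling)


@dataclass(frozen=True)
class GroundTruth:
    """Record sufficient to regenerate a simulated dataset bit-identically."""

    informative_regions: tuple[int, ...]
    realized_effect_sizes: Mapping[int, float]
    seed: int
    parameters: Mapping[str, object]

    def to_dict(self) -> dict:
        return {
            "informative_regions": list(self.informative_regions),
            "realized_effect_sizes": {str(k): float(v) for k, v in self.realized_effect_sizes.items()},
            "seed": int(self.seed),
            "parameters": dict(self.parameters),
        }


@dataclass
class BoldRun:
    """One subject-condition 4D BOLD time series (x, y, z, t)."""

    data: np.ndarray
    tr: float
    subject_id: str
    condition: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("BoldRun.data must be 4-dimensional (x, y, z, t)")
        if self.data.shape[-1] < 16:
            raise ValueError("time series must have at least 16 points")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun.data contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    def copy_with(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(data=data, tr=self.tr, subject_id=self.subject_id, condition=self.condition)


@dataclass
class Parcellation:
    """3D integer label volume (0 = outside mask) plus an ordered region table."""

    labels: np.ndarray
    region_table: list[tuple[int, str]]
    voxel_size: float = 3.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        present = sorted(int(v) for v in np.unique(self.labels) if v != 0)
        table_labels = [int(l) for l, _ in self.region_table]
        if table_labels != present:
            raise ValueError("region_table labels must equal the sorted nonzero labels of the volume")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    @property
    def region_labels(self) -> list[int]:
        return [int(l) for l, _ in self.region_table]

    def region_name(self, label: int) -> str:
        for l, name in self.region_table:
            if l == label:
                return name
        raise KeyError(f"no region with label {label}")


@dataclass
class VoxelMap:
    """A per-voxel feature volume, finite exactly on its mask."""

    values: np.ndarray
    mask: np.ndarray
    feature_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("map contains non-finite values inside the mask")


@dataclass
class RegionVector:
    """Region-mean feature values ordered by the parcellation's region table."""

    values: np.ndarray
    region_labels: list[int]
    feature_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if len(self.values) != len(self.region_labels):
            raise ValueError("length of values must equal number of regions")


@dataclass
class FeatureTable:
    """Samples x regions feature matrix with condition labels and subject ids.

    Rows are ordered subject-major, hunger before satiety within each subject,
    so the study design yields a 48 x 90 table (24 subjects x 2 conditions).
    """

    X: np.ndarray
    y: np.ndarray
    subject_id: np.ndarray
    region_labels: list[int]
    feature_kind: str = ""
    conditions: tuple[str, str] = CONDITIONS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=object)
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.y) != self.X.shape[0] or len(self.subject_id) != self.X.shape[0]:
            raise ValueError("y and subject_id must have one entry per row of X")
        if self.X.shape[1] != len(self.region_labels):
            raise ValueError("region_labels must have one entry per column of X")
        present = set(self.y.tolist())
        if not present.issubset(set(self.conditions)):
            raise ValueError(f"labels {present} not a subset of conditions {self.conditions}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_regions(self) -> int:
        return self.X.shape[1]

    def column_index(self, labels: Sequence[int]) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.region_labels)}
        try:
            return np.array([lookup[int(l)] for l in labels], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"region label {exc} not present in table") from exc

    def numeric_labels(self, positive: str = HUNGER) -> np.ndarray:
        """+1 for the positive (hunger) class, -1 otherwise."""
        return np.where(self.y == positive, 1.0, -1.0)

    def with_labels(self, y: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            X=self.X, y=np.asarray(y, dtype=object), subject_id=self.subject_id,
            region_labels=list(self.region_labels), feature_kind=self.feature_kind,
            conditions=self.conditions,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"R{l:03d}": self.X[:, i] for i, l in enumerate(self.region_labels)}
        return pd.DataFrame({"subject": self.subject_id, "condition": self.y, **cols})


@dataclass(frozen=True)
class SvmConfig:
    """Linear soft-margin SVM configuration for the LOOCV criterion.

    The study does not report its SVM hyperparameters; C = 1 with
    training-fold z-scoring is the package default and is echoed into every
    report.  ``engine`` selects the in-package dual coordinate-descent solver
    (``fast``) or scikit-learn's liblinear wrapper (``sklearn``); the two are
    cross-checked against each other in the test suite.
    """

    C: float = 1.0
    standardize: bool = True
    positive_class: str = HUNGER
    engine: str = "fast"
    tol: float = 1e-8
    max_passes: int = 100_000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.engine not in ("fast", "sklearn"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion matrix, rows = classified, columns = reference.

    Layout [[TP, FP], [FN, TN]] with hunger as the positive class: TP counts
    hunger scans classified as hunger.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=int)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class MetricsReport:
    """Classification accuracy (CA), sensitivity, specificity and error rate.

    Raw values are exact fractions; ``display`` applies the reporting
    convention of rounding percentages to the nearest integer (half away from
    zero) and the error rate to two decimals.  A metric with a zero
    denominator is ``None`` (undefined), never 0.
    """

    ca: float | None
    sen: float | None
    spe: float | None
    er: float | None

    @staticmethod
    def _round_half_up(x: float, ndigits: int) -> float:
        scale = 10 ** ndigits
        return float(np.floor(x * scale + 0.5) / scale)

    @property
    def display(self) -> dict:
        out: dict[str, float | None] = {}
        for key, val in (("ca_pct", self.ca), ("sen_pct", self.sen), ("spe_pct", self.spe)):
            out[key] = None if val is None else int(self._round_half_up(100 * val, 0))
        out["er"] = None if self.er is None else self._round_half_up(self.er, 2)
        return out

    def to_dict(self) -> dict:
        return {"ca": self.ca, "sen": self.sen, "spe": self.spe, "er": self.er,
                "display": self.display}


@dataclass
class SelectionStep:
    action: str  # "add" or "remove"
    label: int
    subset: tuple[int, ...]
    criterion: float


@dataclass
class SelectionTrace:
    """Ordered record of a sequential search, with the best subset per size."""

    steps: list[SelectionStep] = field(default_factory=list)
    best_per_size: dict[int, tuple[tuple[int, ...], float]] = field(default_factory=dict)
    final_subset: tuple[int, ...] = ()
    final_criterion: float = float("nan")
    n_evaluations: int = 0
    budget_exhausted: bool = False
    strategy: str = ""

    def to_dict(self, region_names: Mapping[int, str] | None = None) -> dict:
        name = (lambda l: region_names.get(l, str(l))) if region_names else str
        return {
            "strategy": self.strategy,
            "steps": [
                {"action": s.action, "label": s.label, "name": name(s.label),
                 "subset": list(s.subset), "criterion": s.criterion}
                for s in self.steps
            ],
            "best_per_size": {
                str(k): {"subset": list(sub), "criterion": crit}
                for k, (sub, crit) in sorted(self.best_per_size.items())
            },
            "final_subset": list(self.final_subset),
            "final_subset_names": [name(l) for l in self.final_subset],
            "final_criterion": self.final_criterion,
            "n_evaluations": self.n_evaluations,
            "budget_exhausted": self.budget_exhausted,
        }


@dataclass
class PermutationNull:
    """Null distribution of LOOCV error rates under label permutation."""

    null_errors: np.ndarray
    observed_error: float
    n_perm: int
    p_value: float
    mode: str
    scheme: str
    seed: int

    def summary(self, n_bins: int = 20) -> dict:
        hist, edges = np.histogram(self.null_errors, bins=n_bins, range=(0.0, 1.0))
        return {
            "observed_error": self.observed_error,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "mode": self.mode,
            "scheme": self.scheme,
            "seed": self.seed,
            "null_mean": float(np.mean(self.null_errors)),
            "null_hist_counts": hist.tolist(),
            "null_hist_edges": edges.tolist(),
        }
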