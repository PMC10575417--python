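"""Reconstruction quality metrics.

The headline metric is the Pearson correlation (PC) between the true and
reconstructed velocity maps, computed over all cells of the image,

    PC = sum (X_i - mean X)(Y_i - mean Y)
         / sqrt( sum (X_i - mean X)^2 * sum (Y_i - mean Y)^2 ).

Whole-image PC is partly carried by the static skull/water background, which
every reconstruction shares; a clot-region-only PC is therefore reported
alongside, together with an (optional) clot-localization error: the distance
between the true clot center and the centroid of cells whose predicted
velocity deviates from the tissue background by more than half the clot
contrast. Per-sample PCs are aggregated overall and in clot-diameter bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .network import Model, predict
from .phantom import ClotSpec

__all__ = [
    "ReconstructionReport",
    "SizeBin",
    "pearson_cc",
    "evaluate_testset",
    "bin_by_size",
]


def pearson_cc(X: np.ndarray, Y: np.ndarray) -> float:
    """Pearson correlation over all flattened entries of two equal-shape maps."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    x = X.ravel() - X.mean()
    y = Y.ravel() - Y.mean()
    sx = float(np.sqrt(np.sum(x * x)))
    sy = float(np.sqrt(np.sum(y * y)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("Pearson correlation undefined: an input has zero variance")
    return float(np.clip(np.dot(x, y) / (sx * sy), -1.0, 1.0))


@dataclass
class SizeBin:
    lo: float  # mm, exclusive
    hi: float  # mm, inclusive (inf for the open top bin)
    count: int
    mean_pc: Optional[float]  # None for an empty bin

    def label(self) -> str:
        return f"({self.lo:g}, {self.hi:g}] mm" if math.isfinite(self.hi) else f"> {self.lo:g} mm"


@dataclass
class ReconstructionReport:
    """Per-sample and aggregate reconstruction statistics."""

    pc: List[Optional[float]]  # None for samples where evaluation failed
    clot_diameter: List[Optional[float]]  # mm
    clot_pc: List[Optional[float]] = field(default_factory=list)  # clot-region-only
    centroid_error_mm: List[Optional[float]] = field(default_factory=list)
    failures: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.pc)

    @property
    def mean_pc(self) -> float:
        vals = [p for p in self.pc if p is not None]
        if not vals:
            raise ValueError("no successfully evaluated samples")
        return float(np.mean(vals))

    @property
    def best_pc(self) -> float:
        return float(max(p for p in self.pc if p is not None))

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_samples": self.n_samples,
                "mean_pc": self.mean_pc,
                "best_pc": self.best_pc,
                "per_sample": [
                    {
                        "pc": self.pc[i],
                        "clot_diameter_mm": self.clot_diameter[i],
                        "clot_pc": self.clot_pc[i] if self.clot_pc else None,
                        "centroid_error_mm": (
                            self.centroid_error_mm[i] if self.centroid_error_mm else None
                        ),
                    }
                    for i in range(self.n_samples)
                ],
                "failures": self.failures,
            },
            indent=2,
        )

    def to_table(self) -> str:
        lines = ["sample\tdiameter_mm\tpc\tclot_pc\tcentroid_err_mm"]
        for i in range(self.n_samples):
            d = self.clot_diameter[i]
            cpc = self.clot_pc[i] if self.clot_pc else None
            ce = self.centroid_error_mm[i] if self.centroid_error_mm else None
            fmt = lambda v: "NA" if v is None else f"{v:.6g}"
            lines.append(f"{i}\t{fmt(d)}\t{fmt(self.pc[i])}\t{fmt(cpc)}\t{fmt(ce)}")
        return "\n".join(lines)


def _clot_centroid_error(
    pred: np.ndarray,
    clot: ClotSpec,
    tissue_mask: np.ndarray,
    tissue_velocity: float,
    spacing: float,
) -> Optional[float]:
    """Distance (mm) from the true clot center to the centroid of predicted
    clot-like cells (deviation from tissue > half the clot contrast), searched
    inside the tissue region."""
    contrast = abs(clot.velocity - tissue_velocity)
    if contrast == 0:
        return None
    dev = np.abs(pred - tissue_velocity) > 0.5 * contrast
    cand = dev & tissue_mask
    if not cand.any():
        return None
    idx = np.nonzero(cand)
    centroid = np.array([(i.mean() + 0.5) * spacing for i in idx])
    return float(np.linalg.norm(centroid - np.asarray(clot.center)))


def evaluate_testset(
    model: Model,
    features: Sequence,
    labels: Sequence[np.ndarray],
    clot_specs: Optional[Sequence[ClotSpec]] = None,
    tissue_mask: Optional[np.ndarray] = None,
    tissue_velocity: float = 1540.0,
    spacing: float = 1.0,
) -> ReconstructionReport:
    """Predict every sample and score it; per-sample failures do not abort.

    ``tissue_mask`` (the static tissue-interior mask of the phantom, clot
    cells included) enables the clot-region PC and the centroid-error metric;
    it is shared by all samples since the skull geometry is fixed.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must be aligned")
    if clot_specs is not None and len(clot_specs) != len(labels):
        raise ValueError("clot_specs must align with labels")

    report = ReconstructionReport(pc=[], clot_diameter=[], clot_pc=[], centroid_error_mm=[])
    for i, (feat, lab) in enumerate(zip(features, labels)):
        clot = clot_specs[i] if clot_specs is not None else None
        report.clot_diameter.append(clot.diameter if clot is not None else None)
        try:
            pred = predict(model, feat)
            lab = np.asarray(lab, dtype=np.float64)
            report.pc.append(pearson_cc(lab, pred))
            if tissue_mask is not None:
                report.clot_pc.append(pearson_cc(lab[tissue_mask], pred[tissue_mask]))
                if clot is not None:
                    report.centroid_error_mm.append(
                        _clot_centroid_error(pred, clot, tissue_mask, tissue_velocity, spacing)
                    )
                else:
                    report.centroid_error_mm.append(None)
            else:
                report.clot_pc.append(None)
                report.centroid_error_mm.append(None)
        except (ValueError, RuntimeError) as exc:
            report.pc.append(None)
            report.clot_pc.append(None)
            report.centroid_error_mm.append(None)
            report.failures.append((i, str(exc)))
    return report


def bin_by_size(report: ReconstructionReport, bin_edges: Sequence[float]) -> List[SizeBin]:
    """Aggregate per-sample PC into clot-diameter bins.

    ``bin_edges`` are ascending diameters in mm; bin b collects diameters in
    (edge_b, edge_{b+1}], i.e. a diameter exactly on an edge goes to the lower
    bin, and the last bin is open-ended. Empty bins carry mean None.
    """
    edges = list(bin_edges)
    if any(later <= earlier for later, earlier in zip(edges[1:], edges)):
        raise ValueError("bin_edges must be strictly ascending")
    bounds = [(edges[i], edges[i + 1] if i + 1 < len(edges) else math.inf)
              for i in range(len(edges))]
    bins = []
    for bi, (lo, hi) in enumerate(bounds):
        def _in(d: float) -> bool:
            return (d == lo and bi == 0) or lo < d <= hi  # first bin closed below
        vals = [
            report.pc[i]
            for i in range(report.n_samples)
            if report.pc[i] is not None
            and report.clot_diameter[i] is not None
            and _in(report.clot_diameter[i])
        ]
        bins.append(SizeBin(lo=lo, hi=hi, count=len(vals),
                            mean_pc=float(np.mean(vals)) if vals else None))
    return bins
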