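"""Interface ground truth and point-level evaluation of probability fields.

A surface vertex is an interface point when it lies within 1.6 Å of the van
der Waals surface of any bound-ligand atom.  Predictions are scored by
threshold sweeps: ROC curves with trapezoidal area, and precision–recall
curves with step-wise area (no trapezoids, which are optimistic for PR).
Tied probabilities cross the threshold together — ties are common after
group expansion copies one representative value onto many vertices.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn import metrics as _metrics

from .chemistry import Atom
from .geometry import TriangleMesh
from .prediction import PredictConfig, predict_ligand

INTERFACE_CUTOFF = 1.6  # Å from the ligand atoms' vdW surface


@dataclasses.dataclass
class EvalSummary:
    """ROC and/or PR curves with their areas and the thresholds swept."""

    roc_points: np.ndarray | None = None   # (k, 2) fpr, tpr
    roc_area: float | None = None
    pr_points: np.ndarray | None = None    # (k, 2) recall, precision
    pr_area: float | None = None
    thresholds: np.ndarray | None = None


def label_interface(
    mesh: TriangleMesh, ligand_atoms: list, cutoff: float = INTERFACE_CUTOFF
) -> np.ndarray:
    """Boolean interface labels per vertex (vdW-surface distance ≤ cutoff)."""
    if not ligand_atoms:
        warnings.warn("no ligand atoms: all interface labels false", stacklevel=2)
        return np.zeros(mesh.n_vertices, dtype=bool)
    d = np.full(mesh.n_vertices, np.inf)
    for a in ligand_atoms:
        d = np.minimum(d, np.linalg.norm(mesh.vertices - a.position, axis=1) - a.vdw_radius)
    return d <= cutoff + 1e-12


def _check_values(field) -> np.ndarray:
    values = np.asarray(getattr(field, "values", field), dtype=float)
    if values.ndim != 1:
        raise ValueError("field must be a 1-D per-sample probability array")
    return values


def roc(field, labels: np.ndarray) -> EvalSummary:
    """ROC curve and trapezoidal area from a threshold sweep."""
    values = _check_values(field)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _metrics.roc_curve(labels.astype(int), values)
    return EvalSummary(
        roc_points=np.column_stack([fpr, tpr]),
        roc_area=float(_metrics.auc(fpr, tpr)),
        thresholds=thr,
    )


def precision_recall(field, labels: np.ndarray) -> EvalSummary:
    """PR curve and step-wise (average-precision) area."""
    values = _check_values(field)
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("PR curve needs at least one positive label")
    precision, recall, thr = _metrics.precision_recall_curve(labels.astype(int), values)
    ap = float(_metrics.average_precision_score(labels.astype(int), values))
    return EvalSummary(
        pr_points=np.column_stack([recall, precision]),
        pr_area=ap,
        thresholds=thr,
    )


def sensitivity_at_specificity(field, labels: np.ndarray, target_specificity: float) -> float:
    """Maximum sensitivity among thresholds reaching the target specificity."""
    if not 0.0 <= target_specificity <= 1.0:
        raise ValueError("target specificity must lie in [0, 1]")
    values = _check_values(field)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("needs both classes present")
    fpr, tpr, _ = _metrics.roc_curve(labels.astype(int), values)
    ok = (1.0 - fpr) >= target_specificity - 1e-12
    if not ok.any():
        warnings.warn("target specificity unreachable; returning 0", stacklevel=2)
        return 0.0
    return float(tpr[ok].max())


def confusion_matrix(
    models: list,
    cases: list,
    config: PredictConfig | None = None,
) -> np.ndarray:
    """PR-area matrix: cell (i, j) scores model i's field on case j's truth.

    ``cases`` is a list of (normalized DescriptorSurface, ligand atom list);
    labels come from :func:`label_interface` on each case.
    """
    out = np.zeros((len(models), len(cases)))
    for j, (surface, ligand_atoms) in enumerate(cases):
        labels = label_interface(surface.mesh, ligand_atoms)
        for i, model in enumerate(models):
            result = predict_ligand(surface, model, config)
            out[i, j] = precision_recall(result.field, labels).pr_area
    return out


def heatmap_figure(matrix: np.ndarray, row_labels, col_labels, path) -> None:
    """Optional PR-area heat map (matplotlib imported lazily)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + len(col_labels), 1 + len(row_labels)))
    im = ax.imshow(matrix, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(col_labels)), col_labels, rotation=45, ha="right")
    ax.set_yticks(range(len(row_labels)), row_labels)
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            ax.text(j, i, f"{matrix[i, j]:.2f}", ha="center", va="center", color="w")
    fig.colorbar(im, label="PR area")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
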