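"""Frame-wise agreement between two annotations (or annotation vs classifier).

Agreement is the F1 score computed from frame-wise confusion counts per
behavior, plus a combined score from counts pooled (micro-averaged) across
behaviors; a macro average is reported alongside.  Point-like labels
(proboscis extension, egg out) are annotated on a single frame, so before
comparison they are dilated symmetrically to a small odd width (default 3
frames) in both annotations — a one-frame disagreement in the placement of
an instantaneous event should not count as a miss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .ethogram import LABELS, LABEL_INDEX, Ethogram


@dataclass
class ConfusionTable:
    """Per-behavior frame-wise TP/FP/FN counts plus pooled totals."""

    tp: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int]

    @property
    def combined(self) -> tuple[int, int, int]:
        return (
            sum(self.tp.values()),
            sum(self.fp.values()),
            sum(self.fn.values()),
        )


@dataclass
class AgreementReport:
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    combined_precision: float
    combined_recall: float
    combined_f1: float        # micro-averaged (pooled counts)
    macro_f1: float           # unweighted mean of per-behavior F1


def expand_sparse_labels(
    e: Ethogram, labels: tuple[str, ...] = ("pe", "egg_out"), width: int = 3
) -> Ethogram:
    """Dilate point-like labels symmetrically to ``width`` frames.

    ``width`` must be odd; each active frame becomes a centered run of
    ``width`` frames, clipped at the recording bounds.  ``width=1`` is the
    identity.
    """
    if width % 2 != 1:
        raise ValueError(f"width must be odd, got {width}")
    out = e.copy()
    if width == 1:
        return out
    structure = np.ones(width, dtype=bool)
    for lab in labels:
        j = LABEL_INDEX[lab]
        out.activity[:, j] = binary_dilation(out.activity[:, j], structure=structure)
    return out


def confusion_counts(a: Ethogram, b: Ethogram) -> ConfusionTable:
    """Frame-wise TP/FP/FN of comparison ``b`` against reference ``a``."""
    if a.n_frames != b.n_frames:
        raise ValueError(f"frame count mismatch: {a.n_frames} vs {b.n_frames}")
    tp, fp, fn = {}, {}, {}
    for lab in LABELS:
        ref = a.column(lab)
        cmp_ = b.column(lab)
        tp[lab] = int(np.sum(ref & cmp_))
        fp[lab] = int(np.sum(~ref & cmp_))
        fn[lab] = int(np.sum(ref & ~cmp_))
    return ConfusionTable(tp=tp, fp=fp, fn=fn)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def f1_agreement(ct: ConfusionTable) -> AgreementReport:
    """Precision, recall and F1 per behavior and combined.

    F1 = 2*precision*recall / (precision + recall), with the 0/0 case
    defined as 0 (logged).  The combined score pools counts across
    behaviors (micro average); the macro average is also reported.
    """
    precision, recall, f1 = {}, {}, {}
    for lab in LABELS:
        p, r, f = _prf(ct.tp[lab], ct.fp[lab], ct.fn[lab])
        if ct.tp[lab] + ct.fp[lab] + ct.fn[lab] == 0:
            warnings.warn(f"{lab}: no frames in either annotation; F1 set to 0", stacklevel=2)
        precision[lab], recall[lab], f1[lab] = p, r, f
    cp, cr, cf = _prf(*ct.combined)
    return AgreementReport(
        precision=precision,
        recall=recall,
        f1=f1,
        combined_precision=cp,
        combined_recall=cr,
        combined_f1=cf,
        macro_f1=float(np.mean([f1[lab] for lab in LABELS])),
    )


def compare_ethograms(
    a: Ethogram,
    b: Ethogram,
    expand: tuple[str, ...] = ("pe", "egg_out"),
    width: int = 3,
) -> AgreementReport:
    """Expand point-like labels in both annotations, then score agreement."""
    return f1_agreement(confusion_counts(
        expand_sparse_labels(a, expand, width), expand_sparse_labels(b, expand, width)
    ))
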