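"""Segmentation evaluation: Jaccard similarity and mean bias error.

JS = |RS intersect TS| / |RS union TS| measures overlap accuracy;
MBE = (|RS| - |TS|) / |RS| is the signed relative region-size bias
(positive: under-segmentation, negative: over-segmentation), with RS
the reference (ground-truth) region and TS the test segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "jaccard", "mean_bias_error", "evaluate_set"]


@dataclass
class EvalReport:
    """Per-image and average segmentation scores for an image set."""

    names: list[str]
    js: list[float]
    mbe: list[float]

    @property
    def n_images(self) -> int:
        return len(self.names)

    @property
    def mean_js(self) -> float:
        return float(np.mean(self.js))

    @property
    def mean_mbe(self) -> float:
        return float(np.mean(self.mbe))

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "mean_js": self.mean_js,
            "mean_mbe": self.mean_mbe,
            "per_image": [
                {"name": n, "js": j, "mbe": m}
                for n, j, m in zip(self.names, self.js, self.mbe)
            ],
        }


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask) > 0


def jaccard(reference: np.ndarray, test: np.ndarray) -> float:
    """Jaccard similarity (intersection over union) of two binary masks."""
    rs, ts = _as_bool(reference), _as_bool(test)
    if rs.shape != ts.shape:
        raise ValueError(f"shape mismatch: {rs.shape} vs {ts.shape}")
    union = np.logical_or(rs, ts).sum()
    if union == 0:
        logger.warning("both masks empty; Jaccard defined as 1.0")
        return 1.0
    return float(np.logical_and(rs, ts).sum() / union)


def mean_bias_error(reference: np.ndarray, test: np.ndarray,
                    mode: str = "signed_size") -> float:
    """Relative region-size bias (|RS| - |TS|) / |RS|.

    ``mode='set_difference'`` instead uses |RS \\ TS| / |RS| (the
    unsigned missed-region fraction).
    """
    rs, ts = _as_bool(reference), _as_bool(test)
    if rs.shape != ts.shape:
        raise ValueError(f"shape mismatch: {rs.shape} vs {ts.shape}")
    n_ref = int(rs.sum())
    if n_ref == 0:
        raise ValueError("reference mask is empty; bias error undefined")
    if mode == "signed_size":
        return float((n_ref - int(ts.sum())) / n_ref)
    if mode == "set_difference":
        return float(np.logical_and(rs, ~ts).sum() / n_ref)
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_set(
    pairs: list[tuple[np.ndarray, np.ndarray]] | dict,
    mode: str = "signed_size",
) -> EvalReport:
    """Evaluate a set of (reference, test) mask pairs.

    ``pairs`` may be a list of tuples or a mapping name -> (ref, test).
    Per-pair failures are re-raised with the pair's identifier.
    """
    if isinstance(pairs, dict):
        items = list(pairs.items())
    else:
        items = [(str(i), p) for i, p in enumerate(pairs)]
    if not items:
        raise ValueError("need at least one mask pair")
    names, js, mbe = [], [], []
    for name, (ref, test) in items:
        try:
            js.append(jaccard(ref, test))
            mbe.append(mean_bias_error(ref, test, mode=mode))
        except ValueError as exc:
            raise ValueError(f"image {name!r}: {exc}") from exc
        names.append(name)
    return EvalReport(names=names, js=js, mbe=mbe)
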