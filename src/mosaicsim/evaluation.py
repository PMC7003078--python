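"""Accuracy metric for inferred local ancestry, with a random baseline.

The per-cell accuracy for true dosages ``z`` and inferred proportions
``x`` over ``S`` sources is ``1 - sum_s |z_s - x_s| / 2``, which lies in
[0, 1] because both vectors sum to 1.  The overall score averages the
per-cell accuracies over all markers and all individuals belonging to
admixed populations; cells whose true ancestry involves a source absent
from the analyzed dataset can be masked out (missing-source handling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass
class InferredAncestry:
    """Inferred ancestry proportions, shape ``(n_individuals, M, S)``."""

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3:
            raise ParameterError("X must have shape (individuals, M, S)")
        if np.any(self.X < 0):
            raise ParameterError("inferred proportions must be nonnegative")
        if np.any(np.abs(self.X.sum(axis=2) - 1) > 1e-6):
            raise ParameterError("inferred proportions must sum to 1 per cell")


@dataclass
class AccuracyResult:
    alpha_site: np.ndarray      # (individuals, M) per-cell accuracies
    mask: np.ndarray            # boolean, cells included in the average
    alpha_overall: float
    n_included: int


_Z_LEVELS = np.array([0.0, 0.5, 1.0])


def _check_rows(v: np.ndarray, name: str, dosage: bool = False) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(np.abs(v.sum(axis=-1) - 1) > 1e-6):
        raise ParameterError(f"{name} rows must sum to 1")
    if dosage and not np.all(np.isin(np.round(v, 9), _Z_LEVELS)):
        raise ParameterError(f"{name} entries must be in {{0, 0.5, 1}}")
    return v


def alpha_site(z_row, x_row) -> float:
    """Per-cell accuracy ``1 - sum_s |z_s - x_s| / 2`` for one (i, m) cell."""
    z = _check_rows(np.atleast_1d(z_row), "z", dosage=True)
    x = _check_rows(np.atleast_1d(x_row), "x")
    return float(1 - np.abs(z - x).sum() / 2)


def alpha_matrix(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorized per-cell accuracies, shape ``(individuals, M)``."""
    return 1 - np.abs(np.asarray(Z, float) - np.asarray(X, float)).sum(axis=2) / 2


def overall_alpha(Z: np.ndarray, X: np.ndarray, admixed_flags,
                  mask: np.ndarray | None = None) -> AccuracyResult:
    """Average per-cell accuracy over unmasked cells of admixed individuals.

    Source-representative individuals are always excluded; ``mask`` (same
    shape as ``alpha_site``) may exclude further cells, e.g. those with
    true ancestry from a missing source.  Cells are weighted equally.
    """
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    if Z.shape != X.shape:
        raise ParameterError(f"Z shape {Z.shape} != X shape {X.shape}")
    admixed_flags = np.asarray(admixed_flags, dtype=bool)
    if admixed_flags.shape[0] != Z.shape[0]:
        raise ParameterError("admixed_flags length must equal n_individuals")
    site = alpha_matrix(Z, X)
    full_mask = np.broadcast_to(admixed_flags[:, None], site.shape).copy()
    if mask is not None:
        full_mask &= np.asarray(mask, dtype=bool)
    n = int(full_mask.sum())
    if n == 0:
        raise ParameterError("no cells left to average over (empty mask)")
    return AccuracyResult(
        alpha_site=site,
        mask=full_mask,
        alpha_overall=float(site[full_mask].mean()),
        n_included=n,
    )


def random_inference(n_sources: int, n_individuals: int, n_sites: int) -> InferredAncestry:
    """The uniform baseline: every cell gets ``1/S`` for every source."""
    if n_sources < 2:
        raise ParameterError("n_sources must be >= 2")
    x = np.full((n_individuals, n_sites, n_sources), 1.0 / n_sources)
    return InferredAncestry(X=x)


def missing_source_mask(Z_full: np.ndarray, missing_source: int,
                        per_site: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Drop one source from the truth and mask cells that carry it.

    Returns ``(Z_reduced, mask)`` where ``Z_reduced`` drops the missing
    source's column (rows of included cells already sum to 1 since their
    missing-source dosage is 0) and ``mask`` is True for cells to keep.
    By default masking is per (individual, site) cell; ``per_site=True``
    instead excludes a site for all individuals as soon as any individual
    carries the missing ancestry there.
    """
    Z_full = np.asarray(Z_full, dtype=float)
    s_full = Z_full.shape[2]
    if s_full < 2:
        raise ParameterError("need at least 2 sources")
    if not 0 <= missing_source < s_full:
        raise ParameterError("missing_source out of range")
    mask = Z_full[:, :, missing_source] == 0
    if per_site:
        mask = np.broadcast_to(mask.all(axis=0)[None, :], mask.shape).copy()
    if not mask.any():
        raise ParameterError("masking excluded every cell")
    z_reduced = np.delete(Z_full, missing_source, axis=2)
    # renormalize (no-op for included cells; avoids 0-rows for masked ones)
    sums = z_reduced.sum(axis=2, keepdims=True)
    z_reduced = np.divide(z_reduced, sums, out=np.zeros_like(z_reduced),
                          where=sums > 0)
    return z_reduced, mask


# Alternative metrics (evaluated in the study but not headline numbers).


def r2_metric(Z: np.ndarray, X: np.ndarray, admixed_flags,
              mask: np.ndarray | None = None) -> float:
    """Squared sample correlation between true and inferred dosages."""
    keep = _cells(Z, admixed_flags, mask)
    z = np.asarray(Z, float)[keep].ravel()
    x = np.asarray(X, float)[keep].ravel()
    if z.std() == 0 or x.std() == 0:
        return float("nan")
    return float(np.corrcoef(z, x)[0, 1] ** 2)


def mse_metric(Z: np.ndarray, X: np.ndarray, admixed_flags,
               mask: np.ndarray | None = None) -> float:
    keep = _cells(Z, admixed_flags, mask)
    d = np.asarray(Z, float)[keep] - np.asarray(X, float)[keep]
    return float(np.mean(d**2))


def _cells(Z, admixed_flags, mask):
    admixed_flags = np.asarray(admixed_flags, dtype=bool)
    keep = np.broadcast_to(admixed_flags[:, None], Z.shape[:2]).copy()
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    return keep
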