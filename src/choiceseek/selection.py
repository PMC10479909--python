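"""BIC Schwarz-weight model comparison and per-subject selection.

The Schwarz weight of model i among K candidates is

    w_i = exp(-Delta_i / 2) / sum_k exp(-Delta_k / 2),
    Delta_i = BIC_i - min_k BIC_k,

interpretable as the probability that model i is the best of the set in
the BIC sense.  Selection pools every candidate fit for a subject —
including both values of the Q-initialisation hyperparameter — into one
weight computation and takes the argmax, breaking exact ties toward fewer
free parameters and then lexicographic spec name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import ModelSpec
from .fitting import FitResult


class SelectionError(ValueError):
    """Missing or invalid fits for a comparison."""


def schwarz_weights(bics) -> np.ndarray:
    """Normalised exp(-Delta BIC / 2), max-stabilised."""
    b = np.asarray(bics, dtype=float)
    if b.size == 0:
        raise SelectionError("empty BIC list")
    if np.isnan(b).any() or np.isinf(b).any():
        raise SelectionError("non-finite BIC values")
    delta = b - b.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass(frozen=True)
class ComparisonEntry:
    spec: ModelSpec
    bic: float
    delta_bic: float
    weight: float


@dataclass(frozen=True)
class ModelComparison:
    subject_id: str
    entries: tuple[ComparisonEntry, ...]
    selected: ModelSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"subject_id": self.subject_id, "spec": e.spec.name,
             "q_init": e.spec.q_init, "bic": e.bic,
             "delta_bic": e.delta_bic, "weight": e.weight,
             "selected": e.spec == self.selected}
            for e in self.entries
        ])


def select_model(fits: list[FitResult], subject_id: str | None = None,
                 expected_specs: list[ModelSpec] | None = None,
                 ) -> ModelComparison:
    """Pool all candidate fits of one subject into one weight computation.

    ``expected_specs`` (e.g. the 48-model family at both q_init values)
    makes missing fits an error rather than a silent omission.
    """
    if not fits:
        raise SelectionError("no fits to compare")
    if subject_id is None:
        subject_id = fits[0].subject_id
    if expected_specs is not None:
        have = {f.spec for f in fits}
        missing = [s.name for s in expected_specs if s not in have]
        if missing:
            raise SelectionError(f"missing fits for specs: {missing}")
    bics = [f.bic for f in fits]
    weights = schwarz_weights(bics)
    delta = np.asarray(bics) - min(bics)
    entries = tuple(
        ComparisonEntry(f.spec, f.bic, float(d), float(w))
        for f, d, w in zip(fits, delta, weights))
    # argmax weight; ties toward fewer free parameters, then spec name
    best = max(entries,
               key=lambda e: (e.weight, -e.spec.n_free_params, e.spec.name))
    # reverse lexicographic from max(); re-resolve name ties properly
    cands = [e for e in entries if e.weight == best.weight]
    if len(cands) > 1:
        kmin = min(e.spec.n_free_params for e in cands)
        cands = [e for e in cands if e.spec.n_free_params == kmin]
        best = min(cands, key=lambda e: e.spec.name)
    return ModelComparison(subject_id=subject_id, entries=entries,
                           selected=best.spec)


def compare_bonus_vs_bias(fit_bonus: FitResult, fit_bias: FitResult,
                          subject_id: str | None = None) -> ModelComparison:
    """Supplementary two-model comparison: free-choice bonus vs a static
    stage-1 bias, kept outside the 48-model family."""
    if not fit_bonus.spec.has_bonus or not fit_bias.spec.has_static_bias:
        raise SelectionError(
            "expected one bonus spec and one static-bias spec")
    return select_model([fit_bonus, fit_bias], subject_id=subject_id)


def comparisons_to_frame(comparisons: list[ModelComparison]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in comparisons], ignore_index=True)
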