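"""Pipeline expression trees and their execution.

A pipeline is an ordered chain of phases (encoders and/or selectors, each with
its hyperparameter terminal) under exactly one regressor root. Encoders
transform train and apply matrices identically; selector masks are fit on the
training partition only and applied to both, so no information leaks from
evaluation data into feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import (
    EncodingMap,
    RegressorSpec,
    SelectorSpec,
    compose_encodings,
    gf_mask,
    sp_mask,
    vt_mask,
)

__all__ = ["PipelineTree", "EmptyPipelineError", "execute_pipeline"]


class EmptyPipelineError(RuntimeError):
    """Raised when a pipeline's selectors remove every locus."""


@dataclass(frozen=True)
class PipelineTree:
    """An ordered phase chain plus exactly one regressor root."""

    phases: tuple
    root: RegressorSpec

    def __post_init__(self):
        phases = tuple(self.phases)
        for p in phases:
            if not isinstance(p, (EncodingMap, SelectorSpec)):
                raise TypeError(f"phase {p!r} is neither an encoder nor a selector")
        if not isinstance(self.root, RegressorSpec):
            raise TypeError("pipeline root must be a RegressorSpec")
        object.__setattr__(self, "phases", phases)

    def key(self) -> tuple:
        """Structural identity used for deduplication and caching."""
        parts = []
        for p in self.phases:
            if isinstance(p, EncodingMap):
                parts.append(("enc", p.name, p.table))
            else:
                parts.append(("sel", p.kind, p.value))
        return (tuple(parts), self.root.kind, self.root.params)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def encoder_maps(self) -> list:
        return [p for p in self.phases if isinstance(p, EncodingMap)]

    def has_encoder(self) -> bool:
        return any(isinstance(p, EncodingMap) for p in self.phases)

    def has_selector(self) -> bool:
        return any(isinstance(p, SelectorSpec) for p in self.phases)

    def encoding_class(self) -> str:
        """Final inheritance-model class of the composed encoder phases.

        "additive" when no encoder phase is present; otherwise "2-level" /
        "3-level" (/"1-level" for degenerate compositions that collapse every
        genotype to one value) by the number of distinct outputs of the
        composed map.
        """
        encoders = self.encoder_maps()
        if not encoders:
            return "additive"
        return f"{compose_encodings(encoders).n_levels}-level"

    def describe(self) -> str:
        """Human-readable phase chain, e.g. ``Recessive | VT (0.05) | LR``."""
        parts = []
        for p in self.phases:
            if isinstance(p, EncodingMap):
                parts.append(p.name.capitalize())
            else:
                parts.append(f"{p.kind} ({p.value:g})")
        root = self.root.kind
        if self.root.params:
            vals = ", ".join(_fmt(v) for _, v in self.root.params)
            root = f"{root} ({vals})"
        parts.append(root)
        return " | ".join(parts)


def _fmt(v):
    if isinstance(v, bool):
        return "T" if v else "F"
    return f"{v:g}"


def execute_pipeline(tree: PipelineTree, X_train, X_apply=None, y_train=None):
    """Apply the pipeline's phases; return transformed matrices and the mask.

    Returns ``(X_train_t, X_apply_t, mask)`` where ``mask`` is a boolean keep
    flag over the ORIGINAL loci (the cumulative effect of all selector
    phases). ``X_apply_t`` is None when no apply matrix is given. ``y_train``
    is required when the pipeline contains an SP phase, whose F scores are
    computed against the training phenotype.
    """
    Xt = np.asarray(getattr(X_train, "codes", X_train))
    Xa = None if X_apply is None else np.asarray(getattr(X_apply, "codes", X_apply))
    if Xa is not None and Xa.shape[1] != Xt.shape[1]:
        raise ValueError("train and apply matrices must share the locus set")
    m = Xt.shape[1]
    kept = np.arange(m)  # original column indices still present
    for phase in tree.phases:
        if isinstance(phase, EncodingMap):
            Xt = phase.apply(Xt)
            if Xa is not None:
                Xa = phase.apply(Xa)
            continue
        if phase.kind == "VT":
            keep = vt_mask(Xt, phase.value)
        elif phase.kind == "GF":
            keep = gf_mask(Xt, phase.value)
        else:  # SP
            if y_train is None:
                raise ValueError("y_train is required for SP selector phases")
            keep = sp_mask(Xt, np.asarray(y_train, dtype=float), phase.value)
        if not keep.any():
            raise EmptyPipelineError(f"pipeline {tree.describe()!r} removed every locus")
        Xt = Xt[:, keep]
        if Xa is not None:
            Xa = Xa[:, keep]
        kept = kept[keep]
    mask = np.zeros(m, dtype=bool)
    mask[kept] = True
    return Xt, Xa, mask
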