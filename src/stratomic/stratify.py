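"""Consensus misclassification-based re-stratification.

Each model's misclassification probability for an individual is the
fraction of its out-of-fold predictions (across all CV repeats holding the
individual out) that disagree with the pre-assigned label.  An individual
is reassigned when at least ``min_models`` of the five models exceed a
strict probability threshold; the new label is the majority modal
alternative among the flagging models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bench import ModelSpec, build_classifiers, cross_val_oof
from .datatypes import GROUPS, ConfigError, CVScheme, DataError

__all__ = [
    "MisclassMatrix",
    "StratificationResult",
    "misclassification_probability",
    "consensus_reassign",
    "compare_modalities",
]


@dataclass
class MisclassMatrix:
    """Individuals x models misclassification probabilities for one modality.

    ``pred_counts`` holds, per (individual, model), the count of out-of-fold
    predictions per class — enough to recover both the probability and the
    modal alternative class with its frequency.
    """

    modality: str
    probabilities: pd.DataFrame  # index sample, columns model names
    pred_counts: pd.DataFrame  # index (sample, model), columns class names
    pre_labels: pd.Series

    def __post_init__(self) -> None:
        p = self.probabilities.to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise DataError("misclassification probabilities must lie in [0, 1]")

    @property
    def models(self) -> list[str]:
        return list(self.probabilities.columns)

    def modal_alternative(self, sample: str, model: str) -> tuple[str | None, float]:
        """Most common wrong predicted class and its share of all predictions."""
        counts = self.pred_counts.loc[(sample, model)]
        pre = self.pre_labels.loc[sample]
        alt = counts.drop(index=pre)
        total = counts.sum()
        if alt.sum() == 0 or total == 0:
            return None, 0.0
        best = alt.max()
        # ties resolved by the fixed group order
        ordered = [c for c in self.pred_counts.columns if c in alt.index and alt[c] == best]
        ordered.sort(key=lambda c: GROUPS.index(c) if c in GROUPS else len(GROUPS))
        return ordered[0], float(best / total)

    def to_csv(self, path: str | Path) -> None:
        out = self.probabilities.copy()
        out.insert(0, "modality", self.modality)
        out.insert(1, "pre_label", self.pre_labels)
        out.index.name = "sample_id"
        out.to_csv(path)


def misclassification_probability(
    X: pd.DataFrame,
    y_pre: pd.Series,
    scheme: CVScheme,
    specs: Sequence[ModelSpec] | None = None,
    modality: str = "combined",
    seed: int = 0,
) -> MisclassMatrix:
    """Out-of-fold misprediction fractions per individual per model."""
    specs = list(specs) if specs is not None else build_classifiers()
    y_pre = y_pre.reindex(X.index)
    y = y_pre.to_numpy()
    Xv = X.to_numpy(dtype=float)
    prob_cols = {}
    count_rows = []
    for spec in specs:
        classes, pred, _ = cross_val_oof(Xv, y, spec, scheme, seed=seed)
        class_arr = np.array(classes)
        if (pred < 0).any():  # pragma: no cover - complete CV covers every sample
            raise DataError("an individual was never held out")
        y_idx = np.array([classes.index(c) for c in y])
        wrong = pred != y_idx[None, :]
        prob_cols[spec.name] = wrong.mean(axis=0)
        for i, sid in enumerate(X.index):
            counts = {c: int((pred[:, i] == j).sum()) for j, c in enumerate(class_arr)}
            count_rows.append({"sample_id": sid, "model": spec.name, **counts})
    probabilities = pd.DataFrame(prob_cols, index=X.index)
    pred_counts = pd.DataFrame(count_rows).set_index(["sample_id", "model"])
    ordered_classes = [g for g in GROUPS if g in pred_counts.columns] + [
        c for c in pred_counts.columns if c not in GROUPS
    ]
    pred_counts = pred_counts.loc[:, ordered_classes]
    return MisclassMatrix(modality, probabilities, pred_counts, y_pre)


@dataclass
class StratificationResult:
    """Per-individual reassignment decisions plus the cohort-level rate."""

    modality: str
    table: pd.DataFrame  # index sample; pre_label, n_flagged, post_label, reassigned
    threshold: float
    min_models: int

    @property
    def misclassification_rate(self) -> float:
        """Percent of individuals reassigned."""
        return 100.0 * float(self.table["reassigned"].mean())

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "modality", self.modality)
        out.index.name = "sample_id"
        out.to_csv(path)


def consensus_reassign(
    m: MisclassMatrix, threshold: float = 0.5, min_models: int = 3
) -> StratificationResult:
    """Apply the >= min_models-of-five, strictly-above-threshold rule.

    Reassigned individuals take the majority modal alternative class among
    the flagging models; ties break toward the highest mean
    predicted-alternative frequency, then the fixed group order.
    """
    if min_models > len(m.models):
        raise ConfigError(f"min_models={min_models} exceeds the {len(m.models)} models available")
    if m.probabilities.isna().any().any():
        raise DataError("misclassification matrix is incomplete")
    rows = {}
    for sid in m.probabilities.index:
        probs = m.probabilities.loc[sid]
        flagging = [model for model in m.models if probs[model] > threshold]
        pre = m.pre_labels.loc[sid]
        reassigned = len(flagging) >= min_models
        post = pre
        if reassigned:
            votes: dict[str, list[float]] = {}
            for model in flagging:
                alt, freq = m.modal_alternative(sid, model)
                if alt is not None:
                    votes.setdefault(alt, []).append(freq)
            if votes:
                def rank(c: str) -> tuple:
                    order = GROUPS.index(c) if c in GROUPS else len(GROUPS)
                    return (-len(votes[c]), -float(np.mean(votes[c])), order)

                post = min(votes, key=rank)
        rows[sid] = {
            "pre_label": pre,
            "n_flagged": len(flagging),
            "post_label": post,
            "reassigned": reassigned,
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[m.probabilities.index]
    return StratificationResult(m.modality, table, threshold, min_models)


def compare_modalities(results: Mapping[str, StratificationResult]) -> dict:
    """Cross-modality summary: rates, who is reassigned where, concordance."""
    modalities = list(results)
    index_sets = {tuple(r.table.index) for r in results.values()}
    if len(index_sets) != 1:
        raise DataError("modalities cover different individual sets")
    rates = pd.DataFrame(
        {
            "modality": modalities,
            "misclassification_rate": [results[m].misclassification_rate for m in modalities],
            "n_reassigned": [int(results[m].table["reassigned"].sum()) for m in modalities],
            "n_total": [len(results[m].table) for m in modalities],
        }
    )
    agreement = pd.DataFrame(
        {m: results[m].table["reassigned"] for m in modalities}
    )
    concordance = pd.Series(
        {
            m: 100.0 * float((results[m].table["post_label"] == results[m].table["pre_label"]).mean())
            for m in modalities
        },
        name="pre_post_concordance_pct",
    )
    return {"rates": rates, "agreement": agreement, "concordance": concordance}
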