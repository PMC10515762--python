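"""Switch-aware haplotagging accuracy against a truth tagging.

Haplotag labels are arbitrary within a phase set, so predicted reads are
grouped by phase set and, per group, the label orientation (identity or
1<->2 swap) maximizing agreement with truth is chosen before counting
correct reads.  Reads untagged in either input are excluded from the
compared set and reported separately; accuracy is also reported under the
stricter normalization where predicted-untagged truth reads count against
the method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

from .read_tagger import UNTAGGED, HaplotagResult

TagsLike = Union[Iterable[HaplotagResult], Mapping[str, tuple[int, Optional[int]]], Mapping[str, int]]


@dataclass(frozen=True)
class TagComparison:
    """Outcome of comparing a predicted tagging with truth."""

    n_truth_tagged: int
    n_predicted_tagged: int
    n_compared: int  # tagged in both
    n_correct: int  # matches under best per-phase-set orientation
    accuracy: Optional[float]  # percent of compared reads; None if none compared
    untagged_fraction: Optional[float]  # truth-tagged reads we left untagged
    accuracy_vs_truth_tagged: Optional[float]  # percent of all truth-tagged reads

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        keys = list(self.__dict__)
        vals = [self.__dict__[k] for k in keys]
        fmt = ["" if v is None else (f"{v:.4f}" if isinstance(v, float) else str(v)) for v in vals]
        return "\t".join(keys) + "\n" + "\t".join(fmt) + "\n"


def _normalize(tags: TagsLike) -> dict[str, tuple[int, Optional[int]]]:
    if isinstance(tags, Mapping):
        out = {}
        for read_id, value in tags.items():
            if isinstance(value, tuple):
                out[read_id] = (int(value[0]), value[1])
            else:
                out[read_id] = (int(value), None)
        return out
    return {t.read_id: (t.tag, t.phase_set) for t in tags}


def haplotag_accuracy(predicted: TagsLike, truth: TagsLike) -> TagComparison:
    """Compare a predicted read tagging with truth, orientation per phase set.

    ``predicted``/``truth`` accept HaplotagResult lists or read_id -> tag
    (or (tag, phase_set)) mappings.  Truth phase sets are ignored: truth
    labels are taken as globally consistent.
    """
    pred = _normalize(predicted)
    true = _normalize(truth)

    truth_tagged = {r for r, (t, _) in true.items() if t != UNTAGGED}
    pred_tagged = {r for r, (t, _) in pred.items() if t != UNTAGGED}
    compared = truth_tagged & pred_tagged

    by_phase_set: dict[Optional[int], list[str]] = {}
    for read_id in compared:
        by_phase_set.setdefault(pred[read_id][1], []).append(read_id)

    n_correct = 0
    for reads in by_phase_set.values():
        same = sum(1 for r in reads if pred[r][0] == true[r][0])
        n_correct += max(same, len(reads) - same)

    n_compared = len(compared)
    n_truth_tagged = len(truth_tagged)
    return TagComparison(
        n_truth_tagged=n_truth_tagged,
        n_predicted_tagged=len(pred_tagged),
        n_compared=n_compared,
        n_correct=n_correct,
        accuracy=100.0 * n_correct / n_compared if n_compared else None,
        untagged_fraction=(
            (n_truth_tagged - len(truth_tagged & pred_tagged)) / n_truth_tagged
            if n_truth_tagged
            else None
        ),
        accuracy_vs_truth_tagged=(
            100.0 * n_correct / n_truth_tagged if n_truth_tagged else None
        ),
    )
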