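"""Per-view identity matching, cross-view majority voting and evaluation.

Protocol: every enrolled subject contributes one *reference* sequence per
camera view (the gallery) and each query subject one *target* sequence
per view (the probes). Within a view, a probe is assigned the gallery
identity with the minimum DTW feature distance; the per-view decisions
are then aggregated across cameras by majority vote (the statistical mode
of the per-view identities). Two accuracies are reported: without voting,
the fraction of correct (probe, view) decisions; with voting, the
fraction of probes whose voted identity is correct.

Deterministic tie-breaking: within a view, the smallest identity label
wins a distance tie; a tied vote falls to the tied identity with the
smallest summed distance across views (smallest label if distances are
unavailable).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .correlation import correlation_matrix
from .dtw import FeatureKind, feature_distance
from .exceptions import ConfigurationError, NoCandidatesError, NoVotesError
from .kinematics import BodyPart, JointAngleSeries, select_body_part

logger = logging.getLogger(__name__)

#: identity -> view -> JointAngleSeries
AngleDataset = Mapping[str, Mapping[str, JointAngleSeries]]


@dataclass
class Gallery:
    """Precomputed reference features keyed by view, then identity."""

    feature_kind: FeatureKind
    body_part: BodyPart
    entries: dict[str, dict[str, object]] = field(default_factory=dict)

    def add(self, identity: str, view: str, feature) -> None:
        by_id = self.entries.setdefault(str(view), {})
        if identity in by_id:
            raise ConfigurationError(
                f"gallery already holds identity {identity!r} for view {view!r}"
            )
        by_id[identity] = feature

    def views(self) -> list[str]:
        return sorted(self.entries)

    def identities(self, view: str) -> list[str]:
        return sorted(self.entries.get(str(view), {}))


@dataclass
class MatchOutcome:
    """Everything decided for one probe across all of its views."""

    probe_id: str
    per_view_ids: dict[str, str]
    voted_id: str
    per_view_distances: dict[str, dict[str, float]]
    in_gallery: bool = True

    @property
    def correct(self) -> bool:
        return self.voted_id == self.probe_id


@dataclass
class EvaluationReport:
    """Accuracy with and without cross-view voting, plus diagnostics."""

    accuracy_without_voting: float
    accuracy_with_voting: float
    per_view_accuracy: dict[str, float]
    confusion: dict[tuple[str, str], int]
    n_probes: int
    n_pairs: int


def _make_feature(series: JointAngleSeries, feature_kind: FeatureKind,
                  body_part: BodyPart):
    part = select_body_part(series, body_part)
    if feature_kind == "angles":
        return part
    if feature_kind == "correlation":
        return correlation_matrix(part)
    raise ConfigurationError(f"unknown feature kind {feature_kind!r}")


def build_gallery(references: AngleDataset, feature_kind: FeatureKind = "angles",
                  body_part: BodyPart = "whole",
                  views: Sequence[str] | None = None) -> Gallery:
    """Extract the configured feature for every reference (identity, view)."""
    gallery = Gallery(feature_kind=feature_kind, body_part=body_part)
    for identity in sorted(references):
        for view in sorted(references[identity]):
            if views is not None and str(view) not in {str(v) for v in views}:
                continue
            gallery.add(identity, str(view),
                        _make_feature(references[identity][view], feature_kind, body_part))
    return gallery


def match_per_view(probe_feature, gallery: Gallery, view: str) -> tuple[str, dict[str, float]]:
    """Identity with minimum DTW distance in one view; ties -> smallest label.

    Returns (matched identity, distances to every gallery identity).
    """
    view = str(view)
    candidates = gallery.entries.get(view)
    if not candidates:
        raise NoCandidatesError(f"gallery has no entries for view {view!r}")
    distances = {
        identity: feature_distance(feat, probe_feature, gallery.feature_kind)
        for identity, feat in candidates.items()
    }
    best = min(sorted(distances), key=distances.__getitem__)
    return best, distances


def majority_vote(per_view_ids: Mapping[str, str],
                  per_view_distances: Mapping[str, Mapping[str, float]] | None = None) -> str:
    """Mode of the per-view identities.

    A tied mode is resolved in favour of the tied identity with the
    smallest total DTW distance across views, falling back to the
    smallest label when no distances are supplied.
    """
    if not per_view_ids:
        raise NoVotesError("majority_vote received no per-view identities")
    counts = Counter(per_view_ids.values())
    top = max(counts.values())
    tied = sorted(i for i, c in counts.items() if c == top)
    if len(tied) == 1 or per_view_distances is None:
        return tied[0]
    totals = {
        identity: sum(d[identity] for d in per_view_distances.values() if identity in d)
        for identity in tied
    }
    return min(tied, key=lambda i: (totals[i], i))


def evaluate(outcomes: Sequence[MatchOutcome]) -> EvaluationReport:
    """Both accuracy definitions plus per-view breakdown and confusion counts."""
    if not outcomes:
        raise ConfigurationError("evaluate needs at least one match outcome")
    n_pairs = sum(len(o.per_view_ids) for o in outcomes)
    n_correct_pairs = sum(
        1 for o in outcomes for matched in o.per_view_ids.values() if matched == o.probe_id
    )
    per_view_totals: Counter = Counter()
    per_view_correct: Counter = Counter()
    confusion: Counter = Counter()
    for o in outcomes:
        confusion[(o.probe_id, o.voted_id)] += 1
        for view, matched in o.per_view_ids.items():
            per_view_totals[view] += 1
            per_view_correct[view] += matched == o.probe_id
    return EvaluationReport(
        accuracy_without_voting=n_correct_pairs / n_pairs if n_pairs else 0.0,
        accuracy_with_voting=sum(o.correct for o in outcomes) / len(outcomes),
        per_view_accuracy={
            v: per_view_correct[v] / per_view_totals[v] for v in sorted(per_view_totals)
        },
        confusion=dict(confusion),
        n_probes=len(outcomes),
        n_pairs=n_pairs,
    )


def match_probe(target_views: Mapping[str, JointAngleSeries], gallery: Gallery,
                probe_id: str = "",
                view_map: Mapping[str, str] | None = None) -> MatchOutcome:
    """Match one probe in every view it appears in, then vote.

    ``view_map`` optionally redirects a probe view onto a different
    gallery view (cross-view matching); by default each view is matched
    against the same view of the gallery (identical-view protocol).
    """
    per_view_ids: dict[str, str] = {}
    per_view_distances: dict[str, dict[str, float]] = {}
    for view in sorted(target_views, key=str):
        gallery_view = str(view_map.get(str(view), view)) if view_map else str(view)
        feature = _make_feature(target_views[view], gallery.feature_kind, gallery.body_part)
        matched, distances = match_per_view(feature, gallery, gallery_view)
        per_view_ids[str(view)] = matched
        per_view_distances[str(view)] = distances
    voted = majority_vote(per_view_ids, per_view_distances)
    in_gallery = any(probe_id in ids for ids in gallery.entries.values())
    return MatchOutcome(
        probe_id=probe_id,
        per_view_ids=per_view_ids,
        voted_id=voted,
        per_view_distances=per_view_distances,
        in_gallery=in_gallery,
    )


def run_experiment(references: AngleDataset, targets: AngleDataset,
                   feature_kind: FeatureKind = "angles",
                   body_part: BodyPart = "whole",
                   views: Sequence[str] | None = None,
                   view_map: Mapping[str, str] | None = None,
                   ) -> tuple[EvaluationReport, list[MatchOutcome]]:
    """Full pipeline: features -> per-view matching -> vote -> accuracies.

    Target identities absent from the references are still matched (they
    are necessarily wrong) and logged, mirroring incomplete enrolment.
    Deterministic for fixed inputs.
    """
    gallery = build_gallery(references, feature_kind, body_part, views)
    allowed = {str(v) for v in views} if views is not None else None
    outcomes = []
    for identity in sorted(targets):
        target_views = {
            str(v): s for v, s in targets[identity].items()
            if allowed is None or str(v) in allowed
        }
        if not target_views:
            continue
        outcome = match_probe(target_views, gallery, probe_id=identity, view_map=view_map)
        if not outcome.in_gallery:
            logger.warning("target identity %r missing from references; counted incorrect",
                           identity)
        outcomes.append(outcome)
    return evaluate(outcomes), outcomes
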