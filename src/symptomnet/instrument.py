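"""Instrument configuration: items, symptom clusters, and reference marginals.

The default instrument is a 40-item mental-health questionnaire scored 0-3 per
item (higher = more severe), organised into six symptom clusters -- somatization
(7 items, BSI-53 subscale), cognitive function (5, AIDS-HAQ subscale), negative
affect (10, PANAS subscale), interpersonal communication (4, BSI-53 subscale),
cognitive processes (7) and social adaptation (3) -- plus four standalone
symptoms (sleep disturbance, loneliness, sadness, anger).  The module also ships
the published per-item prevalence / severity statistics observed in a
cross-sectional cohort of 503 persons living with HIV, which the synthetic-data
generator uses as calibration targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import InvalidConfigError, MissingItemError

__all__ = [
    "InstrumentConfig",
    "ReferenceItemStat",
    "ReferenceClusterStat",
    "default_instrument",
    "REFERENCE_N",
    "REFERENCE_ITEM_STATS",
    "REFERENCE_CLUSTER_STATS",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Items, labels and cluster membership of an ordinal symptom instrument.

    Parameters
    ----------
    items
        Ordered ``(item_id, label)`` pairs; the item order defines the column
        order of every response matrix and the node order of the single-symptom
        network.
    clusters
        Ordered mapping of cluster name to member item ids.  The cluster order
        defines the node order of the cluster-level network (clusters first,
        then standalone items).
    standalone_items
        Item ids that belong to no cluster but appear as their own nodes in the
        cluster-level network.
    """

    items: tuple[tuple[str, str], ...]
    clusters: Mapping[str, tuple[str, ...]]
    standalone_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.items]
        if len(set(ids)) != len(ids):
            raise InvalidConfigError("duplicate item ids")
        clustered: list[str] = []
        for name, members in self.clusters.items():
            if len(members) == 0:
                raise InvalidConfigError(f"cluster {name!r} is empty")
            clustered.extend(members)
        partition = clustered + list(self.standalone_items)
        if sorted(partition) != sorted(ids):
            raise InvalidConfigError(
                "clusters plus standalone items must partition the item set"
            )
        if len(set(partition)) != len(partition):
            raise InvalidConfigError("an item appears in more than one cluster")

    # -- convenience views -------------------------------------------------
    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.items)

    @property
    def labels(self) -> dict[str, str]:
        return dict(self.items)

    @property
    def cluster_names(self) -> tuple[str, ...]:
        return tuple(self.clusters)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def cluster_items(self, cluster: str) -> tuple[str, ...]:
        try:
            return tuple(self.clusters[cluster])
        except KeyError as exc:  # pragma: no cover - trivial re-raise
            raise MissingItemError(f"unknown cluster {cluster!r}") from exc

    def cluster_network_nodes(self) -> tuple[str, ...]:
        """Node ids of the cluster-level network: clusters then standalone items."""
        return self.cluster_names + self.standalone_items

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "items": [{"id": i, "label": l} for i, l in self.items],
            "clusters": {k: list(v) for k, v in self.clusters.items()},
            "standalone_items": list(self.standalone_items),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InstrumentConfig":
        return cls(
            items=tuple((e["id"], e.get("label", e["id"])) for e in d["items"]),
            clusters={k: tuple(v) for k, v in d.get("clusters", {}).items()},
            standalone_items=tuple(d.get("standalone_items", ())),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "InstrumentConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Default instrument: 40 items in six clusters + 4 standalone symptoms.
# Item order follows the published prevalence table (grouped by cluster);
# cluster order follows the cluster-network figure convention.
# ---------------------------------------------------------------------------

_SOMATIZATION = (
    ("faintness_dizziness", "Faintness or dizziness"),
    ("chest_pain", "Pain in the heart or chest"),
    ("nausea", "Nausea or upset stomach"),
    ("breath_trouble", "Trouble catching your breath"),
    ("hot_cold_spells", "Hot or cold spells"),
    ("numbness_tingling", "Numbness or tingling in parts of your body"),
    ("weakness", "Feeling weak in parts of your body"),
)
_COGNITIVE_FUNCTION = (
    ("concentration_difficulty", "Difficulty concentrating"),
    ("recent_forgetting", "Forgetting things that occurred recently"),
    ("reasoning_difficulty", "Difficulty reasoning"),
    ("confusion", "Becoming confused"),
    ("slow_reactions", "Having slow reactions"),
)
_NEGATIVE_AFFECT = (
    ("distressed", "Distressed"),
    ("upset", "Upset"),
    ("guilty", "Guilty"),
    ("scared", "Scared"),
    ("hostile", "Hostile"),
    ("irritable", "Irritable"),
    ("ashamed", "Ashamed"),
    ("nervous", "Nervous"),
    ("jittery", "Jittery"),
    ("afraid", "Afraid"),
)
_INTERPERSONAL = (
    ("feelings_easily_hurt", "Your feelings are easily hurt"),
    ("people_unfriendly", "Feeling that people are unfriendly or dislike you"),
    ("inferior_to_others", "Feeling inferior to others"),
    ("self_conscious", "Feeling very self-conscious around others"),
)
_COGNITIVE_PROCESSES = (
    ("future_uncertainty", "Uncertainty about the future"),
    ("future_discouraged", "Feeling discouraged about the future"),
    ("punishment_belief", "The belief that I should be punished for my sins"),
    ("lack_of_confidence", "Lack of confidence around others"),
    ("being_watched", "Feeling that I am being watched or talked about by others"),
    ("worthlessness", "Feelings of worthlessness"),
    ("suicidal_ideas", "Suicidal ideas"),
)
_SOCIAL_ADAPTATION = (
    ("escaping_reality", "Escaping from reality"),
    ("social_integration_difficulty", "Unable to integrate into society"),
    ("daily_work_difficulty", "Unable to handle daily work and study"),
)
_STANDALONE = (
    ("sleep_disturbance", "Sleep disturbance"),
    ("loneliness", "Loneliness"),
    ("sadness", "Sadness"),
    ("anger", "Anger"),
)


def default_instrument() -> InstrumentConfig:
    """The canonical 40-item / six-cluster configuration."""
    items = (
        _SOMATIZATION
        + _COGNITIVE_FUNCTION
        + _NEGATIVE_AFFECT
        + _INTERPERSONAL
        + _COGNITIVE_PROCESSES
        + _SOCIAL_ADAPTATION
        + _STANDALONE
    )
    clusters = {
        "somatization": tuple(i for i, _ in _SOMATIZATION),
        "negative_affect": tuple(i for i, _ in _NEGATIVE_AFFECT),
        "cognitive_function": tuple(i for i, _ in _COGNITIVE_FUNCTION),
        "interpersonal_communication": tuple(i for i, _ in _INTERPERSONAL),
        "cognitive_processes": tuple(i for i, _ in _COGNITIVE_PROCESSES),
        "social_adaptation": tuple(i for i, _ in _SOCIAL_ADAPTATION),
    }
    return InstrumentConfig(
        items=items,
        clusters=clusters,
        standalone_items=tuple(i for i, _ in _STANDALONE),
    )


# ---------------------------------------------------------------------------
# Published reference statistics (N = 503 complete cases).  prevalence counts
# are participants scoring >= 1; severity is the per-item mean +- SD of the 0-3
# score.  These are calibration targets for the copula generator and fixtures
# for the rounding worked examples; they are never asserted as outputs of the
# estimation pipeline (the underlying raw data are not deposited).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceItemStat:
    count: int
    prevalence_pct: float
    mean: float
    sd: float


@dataclass(frozen=True)
class ReferenceClusterStat:
    count: int
    prevalence_pct: float
    mean: float
    sd: float
    alpha: float


REFERENCE_N = 503

REFERENCE_ITEM_STATS: dict[str, ReferenceItemStat] = {
    "faintness_dizziness": ReferenceItemStat(194, 38.6, 0.50, 0.73),
    "chest_pain": ReferenceItemStat(136, 27.0, 0.34, 0.63),
    "nausea": ReferenceItemStat(89, 17.7, 0.23, 0.56),
    "breath_trouble": ReferenceItemStat(152, 30.2, 0.41, 0.71),
    "hot_cold_spells": ReferenceItemStat(163, 32.6, 0.45, 0.73),
    "numbness_tingling": ReferenceItemStat(201, 40.0, 0.53, 0.75),
    "weakness": ReferenceItemStat(358, 71.2, 1.02, 0.85),
    "concentration_difficulty": ReferenceItemStat(258, 51.3, 0.75, 0.86),
    "recent_forgetting": ReferenceItemStat(330, 65.6, 0.94, 0.86),
    "reasoning_difficulty": ReferenceItemStat(186, 37.0, 0.50, 0.76),
    "confusion": ReferenceItemStat(183, 36.4, 0.52, 0.79),
    "slow_reactions": ReferenceItemStat(282, 56.1, 0.77, 0.81),
    "distressed": ReferenceItemStat(206, 41.0, 0.63, 0.89),
    "upset": ReferenceItemStat(284, 56.5, 0.84, 0.91),
    "guilty": ReferenceItemStat(224, 44.5, 0.71, 0.94),
    "scared": ReferenceItemStat(233, 46.3, 0.72, 0.92),
    "hostile": ReferenceItemStat(148, 29.4, 0.42, 0.75),
    "irritable": ReferenceItemStat(268, 53.3, 0.81, 0.91),
    "ashamed": ReferenceItemStat(183, 36.4, 0.56, 0.88),
    "nervous": ReferenceItemStat(296, 58.8, 0.88, 0.91),
    "jittery": ReferenceItemStat(269, 53.5, 0.81, 0.92),
    "afraid": ReferenceItemStat(233, 46.3, 0.72, 0.92),
    "feelings_easily_hurt": ReferenceItemStat(234, 46.5, 0.66, 0.83),
    "people_unfriendly": ReferenceItemStat(178, 35.4, 0.47, 0.74),
    "inferior_to_others": ReferenceItemStat(227, 45.1, 0.68, 0.90),
    "self_conscious": ReferenceItemStat(232, 46.1, 0.65, 0.84),
    "future_uncertainty": ReferenceItemStat(322, 64.0, 1.07, 1.01),
    "future_discouraged": ReferenceItemStat(247, 49.1, 0.79, 0.96),
    "punishment_belief": ReferenceItemStat(148, 29.4, 0.44, 0.79),
    "lack_of_confidence": ReferenceItemStat(216, 42.9, 0.65, 0.88),
    "being_watched": ReferenceItemStat(145, 28.8, 0.39, 0.70),
    "worthlessness": ReferenceItemStat(203, 40.4, 0.61, 0.87),
    "suicidal_ideas": ReferenceItemStat(156, 31.0, 0.49, 0.85),
    "escaping_reality": ReferenceItemStat(212, 42.1, 0.63, 0.87),
    "social_integration_difficulty": ReferenceItemStat(154, 30.6, 0.46, 0.80),
    "daily_work_difficulty": ReferenceItemStat(120, 23.9, 0.34, 0.69),
    "sleep_disturbance": ReferenceItemStat(298, 59.2, 0.92, 0.93),
    "loneliness": ReferenceItemStat(285, 56.7, 0.90, 0.98),
    "sadness": ReferenceItemStat(240, 47.7, 0.78, 0.98),
    "anger": ReferenceItemStat(189, 37.6, 0.56, 0.85),
}

# Note: the published somatization cluster row prints 394 (78.5) although
# 394/503 rounds to 78.3; the count and percentage are mutually inconsistent
# at the source.  The count is stored verbatim; computed percentages are
# always derived from counts.
REFERENCE_CLUSTER_STATS: dict[str, ReferenceClusterStat] = {
    "somatization": ReferenceClusterStat(394, 78.5, 3.49, 3.72, 0.868),
    "negative_affect": ReferenceClusterStat(382, 75.9, 7.25, 7.54, 0.953),
    "cognitive_function": ReferenceClusterStat(363, 72.2, 3.48, 3.55, 0.921),
    "interpersonal_communication": ReferenceClusterStat(303, 60.2, 2.45, 2.90, 0.899),
    "cognitive_processes": ReferenceClusterStat(351, 69.8, 4.45, 5.04, 0.915),
    "social_adaptation": ReferenceClusterStat(231, 45.9, 1.43, 2.13, 0.880),
}
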