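"""The seed-domain heuristic: map small-molecule binding to Pfam-A domains.

The heuristic rests on one empirical observation: in proteins made of a
single Pfam-A family, a measured binding interaction can only be mediated
by that family.  Every family observed this way (the sole family of some
protein with a qualifying binding-assay activity) is a validated "seed"
domain.  Multi-domain proteins are then classified by how many distinct
seed families their architecture contains:

  i)   no seed family        -> no mapping,
  ii)  exactly one seed family (any number of copies) -> all qualifying
       activities map to that family,
  iii) two or more distinct seed families -> ambiguous, no mapping.

A qualifying activity is a direct binding-assay measurement (assay type B,
multi- and complex-flags unset) of an allowed activity type, with potency
at least as strong as 50 µM.

`DomainLigandMapper` packages the heuristic as an estimator: ``fit``
derives the seed set and per-target classifications, ``predict`` emits
the activity-to-domain mapping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .io import ActivityRecord, MappingRow, MapType, TargetRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "SeedSet",
    "Provenance",
    "TargetCategory",
    "TargetClassification",
    "DomainLigandMapper",
    "filter_activities",
    "build_seed_set",
    "classify_target",
    "map_activities",
    "cooccurrence_report",
    "DEFAULT_ACTIVITY_TYPES",
    "DEFAULT_LOG_TYPES",
]

#: Controlled activity-type vocabulary for qualifying measurements.
DEFAULT_ACTIVITY_TYPES = frozenset(
    {"Ki", "Kd", "IC50", "EC50", "-Log Ki", "pKd", "pA2", "pI", "pKa"}
)

#: Types reported as -log10(molar); pI/pA2/pKa are treated as log-potency
#: values alongside -Log Ki and pKd because the vocabulary carries one
#: shared potency threshold (noted in logs when compared).
DEFAULT_LOG_TYPES = frozenset({"-Log Ki", "pKd", "pA2", "pI", "pKa"})

_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


@dataclass(frozen=True)
class FilterConfig:
    """Activity-filter settings.

    threshold_concentration is in molar; 5e-5 M corresponds to the 50 µM
    potency cut-off, applied inclusively (a record at exactly 50 µM is
    kept).  Log-scale types are compared against -log10(threshold).
    """

    assay_type_required: str = "B"
    allowed_activity_types: frozenset[str] = DEFAULT_ACTIVITY_TYPES
    threshold_concentration: float = 5e-5
    log_types: frozenset[str] = DEFAULT_LOG_TYPES

    def __post_init__(self) -> None:
        if self.threshold_concentration <= 0:
            raise ValueError("threshold_concentration must be positive")
        if not self.log_types <= self.allowed_activity_types:
            raise ValueError("log_types must be a subset of allowed_activity_types")

    @property
    def log_threshold(self) -> float:
        return -math.log10(self.threshold_concentration)


class Provenance(str, Enum):
    DATA_DERIVED = "data_derived"
    MANUAL = "manual"


@dataclass
class SeedSet:
    """Validated ligand-binding families with provenance per family."""

    provenance: dict[str, Provenance] = field(default_factory=dict)

    @property
    def families(self) -> set[str]:
        return set(self.provenance)

    def __contains__(self, family: str) -> bool:
        return family in self.provenance

    def __len__(self) -> int:
        return len(self.provenance)


class TargetCategory(str, Enum):
    NO_SEED = "no_seed"
    ONE_SEED = "one_seed"
    MULTI_SEED_CONFLICT = "multi_seed_conflict"


@dataclass(frozen=True)
class TargetClassification:
    accession: str
    category: TargetCategory
    mapped_family: str | None = None

    def __post_init__(self) -> None:
        if (self.category is TargetCategory.ONE_SEED) != (self.mapped_family is not None):
            raise ValueError("mapped_family present iff category is one_seed")


# ---------------------------------------------------------------------------
# filtering


def _qualifies(rec: ActivityRecord, config: FilterConfig) -> bool:
    if rec.assay_type != config.assay_type_required:
        return False
    if rec.multi_flag or rec.complex_flag:
        return False
    if rec.activity_type not in config.allowed_activity_types:
        return False
    if not math.isfinite(rec.value):
        return False
    if rec.activity_type in config.log_types:
        # value on the -log10(molar) scale; stronger binding = larger value
        if rec.activity_type in ("pI", "pA2", "pKa"):
            logger.debug(
                "activity %s: type %s compared as log-potency",
                rec.activity_id, rec.activity_type,
            )
        return rec.value >= config.log_threshold
    factor = _UNIT_TO_MOLAR.get(rec.unit)
    if factor is None:
        logger.warning(
            "activity %s: unsupported unit %r for concentration type %s; rejected",
            rec.activity_id, rec.unit, rec.activity_type,
        )
        return False
    return rec.value * factor <= config.threshold_concentration


def filter_activities(
    activities: Iterable[ActivityRecord],
    config: FilterConfig | None = None,
) -> list[ActivityRecord]:
    """Keep qualifying activities: binding assay, unflagged, allowed type,
    potency at least as strong as the threshold (inclusive)."""
    config = config or FilterConfig()
    return [rec for rec in activities if _qualifies(rec, config)]


# ---------------------------------------------------------------------------
# seeding and classification


def build_seed_set(
    targets: Iterable[TargetRecord],
    qualifying: Iterable[ActivityRecord],
    manual_additions: Iterable[str] = (),
    excluded_targets: Iterable[str] = (),
) -> SeedSet:
    """Derive the seed set from single-family targets with qualifying data.

    A target counts as single-family when its architecture contains exactly
    one distinct Pfam family, regardless of copy number.  Excluded targets
    (curated fragment accessions) contribute nothing.  Manual additions are
    kept with ``manual`` provenance unless the data already derives them.
    """
    excluded = set(excluded_targets)
    with_data = {a.target_accession for a in qualifying}
    seeds = SeedSet()
    for target in targets:
        if target.accession in excluded:
            continue
        fams = target.families
        if len(fams) == 1 and target.accession in with_data:
            seeds.provenance[next(iter(fams))] = Provenance.DATA_DERIVED
    for fam in manual_additions:
        seeds.provenance.setdefault(fam, Provenance.MANUAL)
    return seeds


def classify_target(target: TargetRecord, seeds: SeedSet) -> TargetClassification:
    """Apply the three-case rule to one target architecture."""
    seed_fams = sorted(target.families & seeds.families)
    if not seed_fams:
        return TargetClassification(target.accession, TargetCategory.NO_SEED)
    if len(seed_fams) == 1:
        return TargetClassification(
            target.accession, TargetCategory.ONE_SEED, seed_fams[0]
        )
    return TargetClassification(target.accession, TargetCategory.MULTI_SEED_CONFLICT)


def map_activities(
    targets: Mapping[str, TargetRecord] | Iterable[TargetRecord],
    seeds: SeedSet,
    qualifying: Iterable[ActivityRecord],
) -> list[MappingRow]:
    """Emit one MappingRow per qualifying activity on a one-seed target.

    ``maptype`` records whether the target is a single- or multi-domain
    protein (one vs several distinct families overall).  Activities on
    unknown targets are skipped with a warning.  Output is sorted by
    activity_id for determinism.
    """
    if not isinstance(targets, Mapping):
        targets = {t.accession: t for t in targets}
    cls_cache: dict[str, TargetClassification] = {}
    rows: list[MappingRow] = []
    for act in qualifying:
        target = targets.get(act.target_accession)
        if target is None:
            logger.warning("activity %s references unknown target %s; skipped",
                           act.activity_id, act.target_accession)
            continue
        cls = cls_cache.get(target.accession)
        if cls is None:
            cls = classify_target(target, seeds)
            cls_cache[target.accession] = cls
        if cls.category is not TargetCategory.ONE_SEED:
            continue
        assert cls.mapped_family is not None
        maptype = MapType.SINGLE if len(target.families) == 1 else MapType.MULTI
        rows.append(MappingRow(
            activity_id=act.activity_id,
            domain=cls.mapped_family,
            compound_id=act.compound_id,
            target_accession=act.target_accession,
            maptype=maptype,
        ))
    rows.sort(key=lambda r: r.activity_id)
    return rows


# ---------------------------------------------------------------------------
# co-occurrence survey


def cooccurrence_report(
    targets: Iterable[TargetRecord],
    seeds: SeedSet,
    min_count: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survey seed-family conflicts and never-alone families.

    Returns ``(pairs, candidates)``:

    * ``pairs`` — one row per unordered pair of distinct seed families
      co-occurring in a target architecture, with the number of targets in
      which the pair co-occurs (columns family_a, family_b, n_targets).
    * ``candidates`` — families that never occur as the sole family of any
      target, with the number of targets they appear in (columns family,
      n_targets, flagged).  ``flagged`` marks those at or above
      ``min_count``: candidates for manual seed review, the route by which
      Pkinase_Tyr-like families (always fused to other domains) can be
      promoted to seeds.
    """
    targets = list(targets)
    pair_counts: dict[tuple[str, str], int] = {}
    alone: set[str] = set()
    occurrences: dict[str, int] = {}
    for target in targets:
        fams = target.families
        for fam in fams:
            occurrences[fam] = occurrences.get(fam, 0) + 1
        if len(fams) == 1:
            alone.add(next(iter(fams)))
        seed_fams = sorted(fams & seeds.families)
        for i, a in enumerate(seed_fams):
            for b in seed_fams[i + 1:]:
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    pairs = pd.DataFrame(
        [(a, b, n) for (a, b), n in sorted(pair_counts.items())],
        columns=["family_a", "family_b", "n_targets"],
    )
    never_alone = [
        (fam, n, n >= min_count)
        for fam, n in occurrences.items()
        if fam not in alone
    ]
    never_alone.sort(key=lambda t: (-t[1], t[0]))
    candidates = pd.DataFrame(never_alone, columns=["family", "n_targets", "flagged"])
    return pairs, candidates


# ---------------------------------------------------------------------------
# estimator


class DomainLigandMapper(BaseEstimator):
    """Estimator wrapping the seed-domain heuristic.

    Parameters
    ----------
    assay_type : str, default "B"
        Required assay-type code for qualifying activities.
    threshold_molar : float, default 5e-5
        Inclusive potency cut-off in molar (5e-5 M = 50 µM).
    allowed_activity_types, log_types : frozenset of str
        Controlled vocabulary and its log-scale subset.
    manual_seeds : iterable of str, optional
        Families added to the seed set with manual provenance.
    excluded_targets : iterable of str, optional
        Curated accessions (protein fragments) removed before seeding.

    Attributes
    ----------
    seed_set_ : SeedSet
        Validated families with provenance, derived by ``fit``.
    classifications_ : dict accession -> TargetClassification
        Three-case classification of every fitted target.
    n_qualifying_ : int
        Number of activities surviving the filter during ``fit``.
    """

    def __init__(
        self,
        assay_type: str = "B",
        threshold_molar: float = 5e-5,
        allowed_activity_types: frozenset[str] = DEFAULT_ACTIVITY_TYPES,
        log_types: frozenset[str] = DEFAULT_LOG_TYPES,
        manual_seeds: tuple[str, ...] = (),
        excluded_targets: tuple[str, ...] = (),
    ):
        self.assay_type = assay_type
        self.threshold_molar = threshold_molar
        self.allowed_activity_types = allowed_activity_types
        self.log_types = log_types
        self.manual_seeds = manual_seeds
        self.excluded_targets = excluded_targets

    def _filter_config(self) -> FilterConfig:
        return FilterConfig(
            assay_type_required=self.assay_type,
            allowed_activity_types=frozenset(self.allowed_activity_types),
            threshold_concentration=self.threshold_molar,
            log_types=frozenset(self.log_types),
        )

    def fit(
        self,
        targets: Iterable[TargetRecord],
        activities: Sequence[ActivityRecord] = (),
    ) -> "DomainLigandMapper":
        """Filter activities, derive the seed set and classify every target."""
        targets = list(targets)
        config = self._filter_config()
        qualifying = filter_activities(activities, config)
        excluded = set(self.excluded_targets)
        targets = [t for t in targets if t.accession not in excluded]
        self.targets_ = {t.accession: t for t in targets}
        self.seed_set_ = build_seed_set(
            targets, qualifying, self.manual_seeds, excluded
        )
        self.classifications_ = {
            t.accession: classify_target(t, self.seed_set_) for t in targets
        }
        self.n_qualifying_ = len(qualifying)
        return self

    def predict(self, activities: Sequence[ActivityRecord]) -> list[MappingRow]:
        """Map qualifying activities to domains using the fitted seed set."""
        if not hasattr(self, "seed_set_"):
            raise RuntimeError("DomainLigandMapper is not fitted")
        qualifying = filter_activities(activities, self._filter_config())
        qualifying = [a for a in qualifying
                      if a.target_accession not in set(self.excluded_targets)]
        return map_activities(self.targets_, self.seed_set_, qualifying)

    def fit_predict(
        self,
        targets: Iterable[TargetRecord],
        activities: Sequence[ActivityRecord],
    ) -> list[MappingRow]:
        return self.fit(targets, activities).predict(activities)

    def cooccurrence(self, min_count: int = 100) -> tuple[pd.DataFrame, pd.DataFrame]:
        if not hasattr(self, "seed_set_"):
            raise RuntimeError("DomainLigandMapper is not fitted")
        return cooccurrence_report(self.targets_.values(), self.seed_set_, min_count)
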