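"""Synthetic fixtures with planted ground truth.

Generates proteome-style domain architectures, ChEMBL-style activity
tables, binding-site annotations, descriptor tables and discrete
power-law samples, all as pure functions of a config and seed.  The
planted structure (which family of each target binds the ligand, which
families should become seeds, which activities should map where) is
recorded in a :class:`GroundTruth` so downstream modules can be tested
end-to-end without any database export.

The generator emulates the filter-relevant structure of real activity
exports — assay-type codes, aggregation flags, the activity-type
vocabulary, concentration units — and the architecture-relevant
structure of domain annotations (single- vs multi-domain proteins,
repeat domains, linker regions).  It does not mimic real potency value
distributions beyond the threshold dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ActivityRecord, BindingSite, BindingSiteSource, DomainHit, MapType, MappingRow, TargetRecord
from .powerlaw import zeta_sample

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_proteome",
    "generate_activities",
    "generate_binding_sites",
    "generate_powerlaw_sample",
    "generate_descriptors",
    "DEFAULT_DESCRIPTOR_MEANS",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for fixture generation.

    ``p_multidomain`` defaults to 0.5: about half of real drug-target
    dictionaries are multi-domain proteins.  ``family_frequency_alpha``
    shapes how often families recur across targets (heavy-tailed, like
    genomic domain frequencies).  ``noise_fraction`` is the fraction of
    binding-site residues placed outside the planted family; 0 produces
    noise-free sites.  ``rng_seed`` is mandatory: every generator is a
    pure function of config + seed.
    """

    rng_seed: int
    n_targets: int = 200
    n_families: int = 40
    family_frequency_alpha: float = 2.0
    p_multidomain: float = 0.5
    p_liganded_family: float = 0.5
    p_conflict: float = 0.1
    noise_fraction: float = 0.0
    n_binding_residues: int = 10
    activities_per_target: int = 3
    distractor_fraction: float = 0.4

    def __post_init__(self) -> None:
        for name in ("p_multidomain", "p_liganded_family", "p_conflict",
                     "noise_fraction", "distractor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_targets < 1 or self.n_families < 2:
            raise ValueError("need n_targets >= 1 and n_families >= 2")
        if self.family_frequency_alpha <= 1:
            raise ValueError("family_frequency_alpha must exceed 1")


@dataclass
class GroundTruth:
    """Planted structure the generated tables encode."""

    planted_family: dict[str, str] = field(default_factory=dict)
    expected_seed_families: set[str] = field(default_factory=set)
    expected_mappings: dict[int, MappingRow] = field(default_factory=dict)
    liganded_families: set[str] = field(default_factory=set)
    conflict_targets: set[str] = field(default_factory=set)


def _family_names(n: int) -> list[str]:
    return [f"Fam{i:04d}" for i in range(1, n + 1)]


def generate_proteome(
    config: SyntheticConfig,
) -> tuple[dict[str, TargetRecord], list[DomainHit], GroundTruth]:
    """Generate target architectures with planted seed structure.

    Families split into "liganded" (destined to be validated seeds: each
    is forced to appear as at least one single-family target, which
    ``generate_activities`` will endow with a qualifying activity) and
    "dark" families.  Multi-domain targets combine one liganded family
    with dark ones (mappable), several liganded families (planted
    conflicts), or only dark families (unmappable).  Family choice is
    weighted by a heavy-tailed popularity drawn from a discrete power
    law with exponent ``family_frequency_alpha``.  Domain intervals
    within a target never overlap; sequence lengths cover all intervals.
    """
    rng = np.random.default_rng(config.rng_seed)
    families = _family_names(config.n_families)
    n_lig = max(1, int(round(config.p_liganded_family * config.n_families)))
    liganded = families[:n_lig]
    dark = families[n_lig:]
    if not dark:
        raise ValueError("need at least one non-liganded family")
    popularity = zeta_sample(config.family_frequency_alpha, 1,
                             config.n_families, rng).astype(float)
    weight = dict(zip(families, popularity / popularity.sum()))

    truth = GroundTruth(liganded_families=set(liganded))
    targets: dict[str, TargetRecord] = {}
    hits: list[DomainHit] = []

    def _weighted_choice(pool: list[str], size: int) -> list[str]:
        w = np.array([weight[f] for f in pool])
        return list(rng.choice(pool, size=size, replace=False, p=w / w.sum()))

    def _build_target(acc: str, fams: list[str], planted: str | None) -> None:
        # lay domains left to right with random linkers; repeat domains
        # occur with small probability
        pos = int(rng.integers(1, 30))
        arch: list[str] = []
        for f in fams:
            arch.append(f)
            if rng.random() < 0.15:
                arch.append(f)  # tandem copy of the same family
        rng.shuffle(arch)
        domains = []
        for f in arch:
            length = int(rng.integers(60, 200))
            start = pos + int(rng.integers(5, 40))
            domains.append(DomainHit(acc, f, start, start + length - 1))
            pos = start + length - 1
        seq_len = pos + int(rng.integers(5, 60))
        targets[acc] = TargetRecord(acc, domains, seq_len)
        hits.extend(domains)
        if planted is not None:
            truth.planted_family[acc] = planted

    acc_counter = 0

    def _next_acc() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"T{acc_counter:05d}"

    # one guaranteed single-family target per liganded family (the seed anchor)
    for fam in liganded:
        _build_target(_next_acc(), [fam], fam)
    truth.expected_seed_families = set(liganded)

    for _ in range(max(0, config.n_targets - n_lig)):
        acc = _next_acc()
        if rng.random() >= config.p_multidomain:
            fam = _weighted_choice(families, 1)[0]
            _build_target(acc, [fam], fam if fam in truth.expected_seed_families else None)
        elif rng.random() < config.p_conflict and len(liganded) >= 2:
            fams = _weighted_choice(liganded, 2)
            if rng.random() < 0.5 and dark:
                fams += _weighted_choice(dark, 1)
            _build_target(acc, fams, None)
            truth.conflict_targets.add(acc)
        else:
            n_dark = int(rng.integers(1, min(3, len(dark)) + 1))
            fams = _weighted_choice(dark, n_dark)
            if rng.random() < 0.7:
                lig = _weighted_choice(liganded, 1)[0]
                fams.append(lig)
                _build_target(acc, fams, lig)
            else:
                _build_target(acc, fams, None)
    return targets, hits, truth


_ALLOWED_UNITS = ["nM", "uM", "pM"]


def generate_activities(
    targets: dict[str, TargetRecord],
    truth: GroundTruth,
    config: SyntheticConfig,
) -> list[ActivityRecord]:
    """Generate qualifying activities plus known distractors.

    Every target with a planted binding family, and every planted
    conflict target, receives qualifying records (binding assay, flags
    unset, allowed type, potency stronger than or equal to 50 µM).
    Distractors violate exactly one filter dimension each (wrong assay
    type, aggregation flag set, potency too weak, or disallowed activity
    type) and must never appear in the expected mapping.  The expected
    mapping is derived from the planted structure: a qualifying activity
    maps iff its target's architecture contains exactly one distinct
    planted-seed family.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    records: list[ActivityRecord] = []
    act_id = 0
    compound_id = 0
    seeds = truth.expected_seed_families

    def _qualifying(acc: str) -> ActivityRecord:
        nonlocal act_id, compound_id
        act_id += 1
        compound_id += 1
        kind = rng.integers(0, 3)
        if kind == 0:
            # concentration type, value drawn at or below 50 uM
            unit = _ALLOWED_UNITS[int(rng.integers(0, len(_ALLOWED_UNITS)))]
            scale = {"nM": 5e4, "uM": 50.0, "pM": 5e7}[unit]
            value = float(rng.uniform(0.001, 1.0)) * scale
            atype = ["Ki", "Kd", "IC50", "EC50"][int(rng.integers(0, 4))]
            return ActivityRecord(act_id, compound_id, acc, "B", False, False,
                                  atype, round(value, 4), unit)
        if kind == 1:
            # exact-boundary record: 50 uM sharp
            return ActivityRecord(act_id, compound_id, acc, "B", False, False,
                                  "IC50", 50.0, "uM")
        # log-scale type, value above the 4.301 threshold
        atype = ["pKd", "-Log Ki"][int(rng.integers(0, 2))]
        return ActivityRecord(act_id, compound_id, acc, "B", False, False,
                              atype, round(float(rng.uniform(4.31, 9.0)), 3), "")

    def _distractor(acc: str) -> ActivityRecord:
        nonlocal act_id, compound_id
        act_id += 1
        compound_id += 1
        kind = int(rng.integers(0, 4))
        if kind == 0:  # wrong assay type
            return ActivityRecord(act_id, compound_id, acc, "F", False, False,
                                  "Ki", 10.0, "nM")
        if kind == 1:  # aggregation flag set
            multi = bool(rng.integers(0, 2))
            return ActivityRecord(act_id, compound_id, acc, "B", multi, not multi,
                                  "Ki", 10.0, "nM")
        if kind == 2:  # too weak
            return ActivityRecord(act_id, compound_id, acc, "B", False, False,
                                  "Ki", float(rng.uniform(51.0, 500.0)), "uM")
        # disallowed activity type
        return ActivityRecord(act_id, compound_id, acc, "B", False, False,
                              "GI50", 10.0, "nM")

    assayed = sorted(set(truth.planted_family) | truth.conflict_targets)
    for acc in assayed:
        n_q = max(1, int(rng.integers(1, config.activities_per_target + 1)))
        for _ in range(n_q):
            rec = _qualifying(acc)
            records.append(rec)
            seed_fams = targets[acc].families & seeds
            if len(seed_fams) == 1:
                fam = next(iter(seed_fams))
                maptype = (MapType.SINGLE if len(targets[acc].families) == 1
                           else MapType.MULTI)
                truth.expected_mappings[rec.activity_id] = MappingRow(
                    rec.activity_id, fam, rec.compound_id, acc, maptype)
        if rng.random() < config.distractor_fraction:
            records.append(_distractor(acc))
    return records


def generate_binding_sites(
    targets: dict[str, TargetRecord],
    truth: GroundTruth,
    config: SyntheticConfig,
) -> list[BindingSite]:
    """Generate binding sites around each planted family.

    Per target with a planted family: ``k = n_binding_residues`` residues
    sampled (without replacement) inside the planted family's intervals
    and round(k * f / (1 - f)) residues outside them, where f is
    ``noise_fraction``, so the within-family fraction is ~ 1 - f.
    """
    f = config.noise_fraction
    if not 0.0 <= f < 1.0:
        raise ValueError("noise_fraction must be in [0, 1)")
    rng = np.random.default_rng(config.rng_seed + 2)
    k = config.n_binding_residues
    n_out = int(round(k * f / (1.0 - f)))
    sites: list[BindingSite] = []
    for acc in sorted(truth.planted_family):
        target = targets[acc]
        fam = truth.planted_family[acc]
        inside = np.concatenate([
            np.arange(h.start, h.end + 1) for h in target.hits_of(fam)
        ])
        if inside.size < k:
            raise ValueError(
                f"{acc}: planted family interval holds {inside.size} residues, "
                f"need {k}")
        seq = np.arange(1, (target.sequence_length or int(inside.max())) + 1)
        outside = np.setdiff1d(seq, inside)
        if outside.size < n_out:
            raise ValueError(f"{acc}: not enough residues outside the planted family")
        chosen = np.concatenate([
            rng.choice(inside, size=k, replace=False),
            rng.choice(outside, size=n_out, replace=False) if n_out else np.array([], dtype=int),
        ])
        sites.append(BindingSite(acc, frozenset(int(r) for r in chosen),
                                 BindingSiteSource.PDBE, "LIG"))
    return sites


def generate_powerlaw_sample(
    alpha: float, xmin: int, n: int, seed: int | np.random.Generator | None,
) -> np.ndarray:
    """i.i.d. draws from the zeta-normalised discrete power law (inverse CDF)."""
    return zeta_sample(alpha, xmin, n, seed)


#: Realistic per-family descriptor means (mw, alogp, psa, rtb, hbd, hba)
#: for drug-like ligand sets; used as the default planted cluster centres.
DEFAULT_DESCRIPTOR_MEANS = {
    "Pkinase": (420.0, 3.2, 95.0, 5.0, 2.0, 6.0),
    "Trypsin": (480.0, 1.8, 130.0, 8.0, 4.0, 7.0),
    "SNF": (310.0, 2.9, 45.0, 4.0, 1.0, 3.0),
    "p450": (350.0, 4.1, 60.0, 5.0, 1.0, 4.0),
}


def generate_descriptors(
    families: list[str],
    means: np.ndarray | list,
    covariances: np.ndarray | list,
    n_per_family: int,
    seed: int | None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-family multivariate-Gaussian descriptor rows.

    ``means`` is (k, 6); ``covariances`` one (6, 6) matrix shared by all
    families or (k, 6, 6) per family.  Count-valued descriptors (rtb,
    hbd, hba) are rounded and clipped at zero; mw and psa are clipped at
    small positive floors.  Returns (table indexed by molregno, labels).
    """
    rng = np.random.default_rng(seed)
    means = np.asarray(means, dtype=float)
    covariances = np.asarray(covariances, dtype=float)
    if means.shape != (len(families), 6):
        raise ValueError(f"means must be ({len(families)}, 6), got {means.shape}")
    if covariances.shape == (6, 6):
        covariances = np.broadcast_to(covariances, (len(families), 6, 6))
    elif covariances.shape != (len(families), 6, 6):
        raise ValueError("covariances must be (6, 6) or (k, 6, 6)")
    rows, labels, index = [], [], []
    molregno = 0
    for fam, mu, cov in zip(families, means, covariances):
        draws = rng.multivariate_normal(mu, cov, size=n_per_family)
        for d in draws:
            molregno += 1
            mw = max(d[0], 50.0)
            alogp = d[1]
            psa = max(d[2], 0.0)
            rtb, hbd, hba = (int(max(round(v), 0)) for v in d[3:6])
            rows.append((mw, alogp, psa, rtb, hbd, hba))
            labels.append(fam)
            index.append(molregno)
    table = pd.DataFrame(rows, columns=["mw", "alogp", "psa", "rtb", "hbd", "hba"],
                         index=pd.Index(index, name="molregno"))
    return table, pd.Series(labels, index=table.index, name="family")
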