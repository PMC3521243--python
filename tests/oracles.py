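"""Independent brute-force oracles used to cross-check the package.

Everything here is written directly from the scientific rules, without
calling the implementation under test, so agreement is evidence and not
tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import zeta as _zeta

_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "μM": 1e-6,
          "nM": 1e-9, "pM": 1e-12}
_ALLOWED = {"Ki", "Kd", "IC50", "EC50", "-Log Ki", "pKd", "pA2", "pI", "pKa"}
_LOG = {"-Log Ki", "pKd", "pA2", "pI", "pKa"}


def brute_force_qualifies(act, threshold_molar: float = 5e-5) -> bool:
    """Literal re-statement of the activity filter."""
    if act.assay_type != "B" or act.multi_flag or act.complex_flag:
        return False
    if act.activity_type not in _ALLOWED:
        return False
    if act.activity_type in _LOG:
        return act.value >= -math.log10(threshold_molar)
    if act.unit not in _UNITS:
        return False
    return act.value * _UNITS[act.unit] <= threshold_molar


def brute_force_mapping(targets, activities, threshold_molar: float = 5e-5,
                        manual=(), excluded=()):
    """Re-derive seed set and activity mapping from first principles.

    Returns (seed_families, mapping) with mapping a sorted list of tuples
    (activity_id, family, compound_id, accession, maptype).
    """
    targets = {t.accession: t for t in targets if t.accession not in set(excluded)}
    qual = [a for a in activities if brute_force_qualifies(a, threshold_molar)
            and a.target_accession in targets]
    with_data = {a.target_accession for a in qual}
    seeds = set(manual)
    for acc, t in targets.items():
        fams = {d.family for d in t.domains}
        if len(fams) == 1 and acc in with_data:
            seeds |= fams
    mapping = []
    for a in qual:
        t = targets[a.target_accession]
        fams = {d.family for d in t.domains}
        seed_here = fams & seeds
        if len(seed_here) != 1:
            continue  # case i (none) or case iii (conflict): no mapping
        fam = next(iter(seed_here))
        maptype = "single" if len(fams) == 1 else "multi"
        mapping.append((a.activity_id, fam, a.compound_id,
                        a.target_accession, maptype))
    mapping.sort()
    return seeds, mapping


def brute_force_pair_counts(targets, seeds):
    """Count targets containing each unordered pair of distinct seed families."""
    counts: dict[tuple[str, str], int] = {}
    for t in targets:
        fams = sorted({d.family for d in t.domains} & set(seeds))
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                counts[(fams[i], fams[j])] = counts.get((fams[i], fams[j]), 0) + 1
    return counts


def grid_search_alpha(samples, xmin, grid_step=1e-3, lo=1.01, hi=5.0):
    """Dense grid search over the discrete power-law likelihood."""
    tail = np.asarray([s for s in samples if s >= xmin], dtype=float)
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    ll = [-a * np.log(tail).sum() - tail.size * np.log(_zeta(a, xmin))
          for a in grid]
    return float(grid[int(np.argmax(ll))])


def survival_counts(ratios, xs):
    """Proportion of ratios >= x, by direct counting."""
    n = len(ratios)
    return [sum(r >= x for r in ratios) / n for x in xs]


def interval_union_size(intervals):
    """|union| of 1-based inclusive intervals by residue enumeration."""
    residues = set()
    for start, end in intervals:
        residues.update(range(start, end + 1))
    return len(residues)


def eig_pca(X):
    """PCA by explicit eigendecomposition of the sample covariance."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]
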