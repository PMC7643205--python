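"""Benchmark construction and dataset-bias diagnostics.

Covers the three split strategies used to stress-test ligand-based activity
classifiers — seeded random assignment via degenerate scaffolds, strict
scaffold splits (no Murcko scaffold spans train and test), and temporal
splits by publication year — together with two bias audits:

* negative-selection-bias screening of inactive sets (drop compounds whose
  every measurement, against any target, is in the inactive range);
* a Tanimoto similarity audit comparing intra-inactive to active-vs-inactive
  mean similarity with a Welch t-test, which detects inactive sets that are
  trivially separable for structure-only reasons;

plus Fisher exact enrichment of scaffolds between two groups of targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .curation import BioactivityRecord
from .features import ScaffoldKey, ecfp, murcko_scaffold, tanimoto

logger = logging.getLogger(__name__)


@dataclass
class SplitAssignment:
    """Per-compound partition tags and the parameters that produced them."""

    tags: dict[str, str]  # compound_id -> train | validation | test
    kind: str  # random | scaffold | temporal
    parameters: dict = field(default_factory=dict)
    #: compounds dropped (e.g. missing year in a temporal split)
    excluded: list[str] = field(default_factory=list)

    def partition(self, tag: str) -> set[str]:
        return {cid for cid, t in self.tags.items() if t == tag}


def scaffold_split(
    compounds: Mapping[str, str], test_fraction: float = 0.2, seed: int = 0
) -> SplitAssignment:
    """Partition compounds so no Murcko scaffold spans train and test.

    Scaffold groups are assigned greedily, largest first (ties shuffled by
    ``seed``), to a test bin until it would overshoot ``test_fraction``;
    remaining groups go to train.  Disjointness of scaffolds across the two
    sides is exact; the achieved fraction is within the granularity of the
    group sizes.

    Parameters
    ----------
    compounds:
        Mapping of compound_id to SMILES.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    groups: dict[str, list[str]] = {}
    for cid in sorted(compounds):
        key = murcko_scaffold(compounds[cid]).smiles
        groups.setdefault(key, []).append(cid)
    if len(groups) < 2:
        raise ValueError("all compounds share a single scaffold; split impossible")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5CA7]))
    keys = sorted(groups)
    tiebreak = {k: float(r) for k, r in zip(keys, rng.random(len(keys)))}
    ordered = sorted(keys, key=lambda k: (-len(groups[k]), tiebreak[k]))

    target = test_fraction * len(compounds)
    tags: dict[str, str] = {}
    in_test = 0
    for key in ordered:
        members = groups[key]
        side = "test" if in_test + len(members) <= round(target) else "train"
        if side == "test":
            in_test += len(members)
        for cid in members:
            tags[cid] = side
    if in_test == 0:  # every group overshoots; put the smallest group in test
        smallest = min(ordered, key=lambda k: (len(groups[k]), tiebreak[k]))
        for cid in groups[smallest]:
            tags[cid] = "test"
    return SplitAssignment(
        tags, "scaffold", {"test_fraction": test_fraction, "seed": seed}
    )


def temporal_split(
    records: Sequence[BioactivityRecord], cutoff_year: int = 2013
) -> SplitAssignment:
    """Older records train, newer test: year < cutoff -> train, else test.

    Records without a publication year are excluded with a warning.
    """
    tags: dict[str, str] = {}
    excluded: list[str] = []
    for rec in records:
        if rec.doc_year is None:
            excluded.append(rec.compound_id)
            continue
        tags[rec.compound_id] = "train" if rec.doc_year < cutoff_year else "test"
    if excluded:
        logger.warning("temporal split: %d records lack a year and were excluded", len(excluded))
    if tags and not any(t == "test" for t in tags.values()):
        logger.warning("temporal split: no records at or after %d; test set is empty", cutoff_year)
    return SplitAssignment(tags, "temporal", {"cutoff_year": cutoff_year}, excluded)


def negative_bias_filter(
    inactive_ids: Sequence[str],
    activity_table: Sequence[BioactivityRecord],
    active_threshold_nm: float = 10_000.0,
) -> tuple[list[str], list[str]]:
    """Drop inactives with no active-range measurement against any target.

    A compound whose every record (for every target) sits in the inactive
    range carries no evidence that it is a valid, assayable molecule rather
    than a universal non-binder, so it is removed.  Returns
    ``(kept, dropped)`` in input order.
    """
    has_active: set[str] = set()
    seen: set[str] = set()
    for rec in activity_table:
        seen.add(rec.compound_id)
        if rec.standard_value_nm <= active_threshold_nm:
            has_active.add(rec.compound_id)
    kept, dropped = [], []
    for cid in inactive_ids:
        if cid in has_active:
            kept.append(cid)
        else:
            if cid not in seen:
                logger.warning("negative bias filter: %s absent from activity table; dropped", cid)
            dropped.append(cid)
    return kept, dropped


@dataclass(frozen=True)
class BiasAuditReport:
    """Similarity structure of one target's training set."""

    mean_intra_inactive: float
    mean_active_inactive: float
    t_statistic: float
    p_value: float
    #: True when inactives are significantly more self-similar than they are
    #: similar to the actives — the signature of negative selection bias
    biased: bool


def bias_similarity_audit(
    actives: Sequence[str],
    inactives: Sequence[str],
    alpha: float = 0.05,
    max_pairs: int | None = None,
    seed: int = 0,
) -> BiasAuditReport:
    """Tanimoto (ECFP4) audit of a target's active/inactive sets.

    Compares the mean similarity over all inactive–inactive pairs with the
    mean over all active–inactive pairs, using Welch's two-sample t-test at
    the given significance level.  ``max_pairs`` optionally subsamples each
    pair population for very large sets.
    """
    if len(inactives) < 2 or len(actives) < 1:
        raise ValueError("audit needs at least 2 inactives and 1 active")
    from .features import canonical_smiles

    canon_a = [canonical_smiles(s) for s in actives]
    canon_i = [canonical_smiles(s) for s in inactives]
    fps_a = [ecfp(s) for s in actives]
    fps_i = [ecfp(s) for s in inactives]
    intra = np.array([tanimoto(x, y) for x, y in combinations(fps_i, 2)])
    # cross comparison between distinct compounds only: a molecule present in
    # both sets should not contribute trivial self-similarity
    inter = np.array(
        [
            tanimoto(fps_a[i], fps_i[j])
            for i, j in product(range(len(fps_a)), range(len(fps_i)))
            if canon_a[i] != canon_i[j]
        ]
    )
    if inter.size == 0:
        raise ValueError("no distinct active/inactive compound pairs to compare")
    if max_pairs is not None:
        rng = np.random.default_rng(seed)
        if len(intra) > max_pairs:
            intra = intra[rng.choice(len(intra), max_pairs, replace=False)]
        if len(inter) > max_pairs:
            inter = inter[rng.choice(len(inter), max_pairs, replace=False)]
    if np.allclose(intra.mean(), inter.mean()) and np.allclose(np.var(intra), np.var(inter)):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(intra, inter, equal_var=False)
    biased = bool(intra.mean() > inter.mean() and p < alpha)
    return BiasAuditReport(float(intra.mean()), float(inter.mean()), float(t), float(p), biased)


@dataclass(frozen=True)
class ScaffoldEnrichmentRow:
    scaffold: ScaffoldKey
    #: 2x2 table: (group-1 actives, group-2 actives, group-1 inactives, group-2 inactives)
    counts: tuple[int, int, int, int]
    p_value: float
    significant: bool
    #: +1 enriched toward group 1, -1 toward group 2, 0 balanced
    direction: int


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def scaffold_enrichment(
    tables: Mapping[ScaffoldKey, tuple[int, int, int, int]],
    p_threshold: float = 1e-5,
) -> list[ScaffoldEnrichmentRow]:
    """Two-sided Fisher exact test per scaffold occurrence table.

    Each scaffold's table counts its occurrences in the active and inactive
    compound sets of two groups of targets (e.g. targets dominated by one
    method versus another).  Rows with p strictly below ``p_threshold`` are
    flagged; the direction records which group the scaffold leans toward
    (odds-ratio sign of the actives-vs-inactives contrast).
    """
    rows = []
    for key in sorted(tables, key=lambda k: (k.generalized, k.smiles)):
        a, b, c, d = tables[key]
        p = fisher_two_sided(a, b, c, d)
        # direction: compare observed a to its expectation under fixed margins
        expected_a = (a + b) * (a + c) / (a + b + c + d)
        direction = 0 if a == expected_a else (1 if a > expected_a else -1)
        rows.append(
            ScaffoldEnrichmentRow(key, (a, b, c, d), float(p), bool(p < p_threshold), direction)
        )
    return rows


def scaffold_tables_from_datasets(
    group1: Mapping[str, Mapping[str, str]],
    group2: Mapping[str, Mapping[str, str]],
    generalized: bool = False,
) -> dict[ScaffoldKey, tuple[int, int, int, int]]:
    """Build per-scaffold occurrence tables from two groups of target sets.

    Each group maps target_id to {"actives": {cid: smiles}, "inactives": ...}
    style mappings with keys "actives"/"inactives".
    """
    tables: dict[ScaffoldKey, list[int]] = {}

    def _count(group, slot_active: int, slot_inactive: int):
        for _tid, ds in group.items():
            for label, slot in (("actives", slot_active), ("inactives", slot_inactive)):
                for smiles in ds[label].values():
                    key = murcko_scaffold(smiles, generalized=generalized)
                    if not key.smiles:
                        continue
                    tables.setdefault(key, [0, 0, 0, 0])[slot] += 1

    _count(group1, 0, 2)
    _count(group2, 1, 3)
    return {k: tuple(v) for k, v in tables.items()}
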