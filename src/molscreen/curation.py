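"""Bioactivity curation: filtering, aggregation, labelling and negative enrichment.

Turns a raw ChEMBL-style bioactivity table into per-target labelled compound
sets suitable for training binary activity classifiers.  The pipeline stages
are:

1. :func:`filter_records` — keep single-protein targets from allowed taxa,
   binding assays, allowed standard types, and (optionally) records carrying a
   pChEMBL value.
2. :func:`aggregate_duplicates` — collapse replicate measurements of the same
   compound–target pair to their median bioactivity.
3. :func:`label_by_threshold` — actives at <= 10 uM, inactives at >= 20 uM,
   values in between are a gray zone and excluded.
4. :func:`select_modelled_targets` — model only targets with enough actives.
5. :func:`enrich_negatives` — balance inactive sets by borrowing inactives
   from sequence-similar targets (descending identity, with a similarity
   floor), or down-sample excess inactives.

Censored measurements are resolved conservatively: a relation of ``<``/``<=``
only supports the active side of a threshold, ``>``/``>=`` only the inactive
side; records whose relation contradicts the side their value falls on are
dropped.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from statistics import median
from typing import Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO

logger = logging.getLogger(__name__)

TARGET_TYPES = ("single_protein", "other")
ASSAY_TYPES = ("binding", "functional", "other")
STANDARD_TYPES = ("IC50", "EC50", "AC50", "Ki", "Kd", "Potency", "other")
RELATIONS = ("=", "<", ">", "<=", ">=", "missing")

#: relations compatible with calling a measurement active (value bounds from above)
_ACTIVE_RELATIONS = frozenset({"=", "<", "<=", "missing"})
#: relations compatible with calling a measurement inactive (value bounds from below)
_INACTIVE_RELATIONS = frozenset({"=", ">", ">=", "missing"})

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class BioactivityRecord:
    """One experimental measurement linking a compound to a target."""

    compound_id: str
    smiles: str
    target_id: str
    target_type: str = "single_protein"
    taxon: str = "Homo sapiens"
    assay_type: str = "binding"
    standard_type: str = "IC50"
    standard_relation: str = "="
    standard_value_nm: float = 0.0
    pchembl: float | None = None
    doc_year: int | None = None

    def validate(self) -> None:
        if self.target_type not in TARGET_TYPES:
            raise ValueError(f"unknown target_type {self.target_type!r}")
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"unknown assay_type {self.assay_type!r}")
        if self.standard_type not in STANDARD_TYPES:
            raise ValueError(f"unknown standard_type {self.standard_type!r}")
        if self.standard_relation not in RELATIONS:
            raise ValueError(f"unknown standard_relation {self.standard_relation!r}")
        if not (self.standard_value_nm >= 0):
            raise ValueError(f"negative standard_value_nm {self.standard_value_nm}")
        if self.pchembl is not None and not (self.pchembl > 0):
            raise ValueError(f"pchembl must be positive, got {self.pchembl}")


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds and allow-lists for the curation pipeline.

    Defaults follow the canonical large-scale ChEMBL curation recipe:
    actives at <= 10 uM, inactives at >= 20 uM, at least 100 actives per
    modelled target and a 20% sequence-identity floor for negative-set
    enrichment.
    """

    allowed_target_types: frozenset[str] = frozenset({"single_protein"})
    allowed_taxa: frozenset[str] | None = None  # None = any taxon
    allowed_assay_types: frozenset[str] = frozenset({"binding"})
    allowed_standard_types: frozenset[str] = frozenset(
        {"IC50", "EC50", "AC50", "Ki", "Kd", "Potency"}
    )
    active_threshold_nm: float = 10_000.0
    inactive_threshold_nm: float = 20_000.0
    min_actives: int = 100
    similarity_floor_pct: float = 20.0
    require_pchembl: bool = True
    #: keep only the largest fragment of multi-fragment (salt) SMILES
    strip_salts: bool = False

    def __post_init__(self) -> None:
        if not self.active_threshold_nm < self.inactive_threshold_nm:
            raise ValueError("active threshold must lie below the inactive threshold")
        if self.min_actives < 1:
            raise ValueError("min_actives must be >= 1")
        if not 0.0 <= self.similarity_floor_pct <= 100.0:
            raise ValueError("similarity_floor_pct must be in [0, 100]")


@dataclass
class TargetDataset:
    """Labelled compound sets for one target, with enrichment provenance."""

    target_id: str
    actives: dict[str, str] = field(default_factory=dict)  # compound_id -> smiles
    inactives: dict[str, str] = field(default_factory=dict)
    #: (compound_id, donor_target_id, percent identity) per borrowed inactive
    enrichment_provenance: list[tuple[str, str, float]] = field(default_factory=list)
    shortfall: bool = False

    def check_invariants(self) -> None:
        overlap = self.actives.keys() & self.inactives.keys()
        if overlap:
            raise ValueError(f"{self.target_id}: compounds in both classes: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# pipeline stages


def _record_passes(rec: BioactivityRecord, config: CurationConfig) -> bool:
    if rec.target_type not in config.allowed_target_types:
        return False
    if config.allowed_taxa is not None and rec.taxon not in config.allowed_taxa:
        return False
    if rec.assay_type not in config.allowed_assay_types:
        return False
    if rec.standard_type not in config.allowed_standard_types:
        return False
    if config.require_pchembl and rec.pchembl is None:
        return False
    return True


def filter_records(
    records: Sequence[BioactivityRecord], config: CurationConfig
) -> list[BioactivityRecord]:
    """Keep records passing every attribute filter, preserving input order."""
    for i, rec in enumerate(records):
        try:
            rec.validate()
        except ValueError as exc:
            raise ValueError(f"malformed record at index {i}: {exc}") from exc
    return [rec for rec in records if _record_passes(rec, config)]


def aggregate_duplicates(records: Sequence[BioactivityRecord]) -> list[BioactivityRecord]:
    """Collapse replicate (compound, target) measurements to their median.

    The surviving record's non-value fields come from the replicate whose
    value lies closest to the median (ties broken by input order); its
    ``standard_value_nm`` is set to the median itself.  Medians of an even
    number of replicates are the mean of the central pair.  Idempotent.
    """
    groups: dict[tuple[str, str], list[tuple[int, BioactivityRecord]]] = {}
    for i, rec in enumerate(records):
        groups.setdefault((rec.compound_id, rec.target_id), []).append((i, rec))
    out: list[BioactivityRecord] = []
    for key in groups:
        members = groups[key]
        med = float(median(rec.standard_value_nm for _, rec in members))
        rep = min(members, key=lambda item: (abs(item[1].standard_value_nm - med), item[0]))[1]
        out.append(replace(rep, standard_value_nm=med))
    return out


def label_by_threshold(
    records: Sequence[BioactivityRecord], config: CurationConfig
) -> dict[str, TargetDataset]:
    """Assign active/inactive labels per target by the bioactivity thresholds.

    Values strictly between the two thresholds (the gray zone) are excluded,
    as are censored records whose relation contradicts the threshold side.
    """
    datasets: dict[str, TargetDataset] = {}
    for rec in records:
        ds = datasets.setdefault(rec.target_id, TargetDataset(rec.target_id))
        v = rec.standard_value_nm
        if v <= config.active_threshold_nm:
            if rec.standard_relation in _ACTIVE_RELATIONS:
                ds.actives[rec.compound_id] = rec.smiles
        elif v >= config.inactive_threshold_nm:
            if rec.standard_relation in _INACTIVE_RELATIONS:
                ds.inactives[rec.compound_id] = rec.smiles
        # gray zone: excluded
    for ds in datasets.values():
        ds.check_invariants()
    return datasets


def select_modelled_targets(
    datasets: Mapping[str, TargetDataset], config: CurationConfig
) -> list[str]:
    """Targets with at least ``min_actives`` active ligands, sorted by id."""
    return sorted(t for t, ds in datasets.items() if len(ds.actives) >= config.min_actives)


# ---------------------------------------------------------------------------
# sequence identity and negative enrichment


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity between two protein sequences over a global alignment.

    Needleman–Wunsch with match +1, mismatch −1, affine gaps (open −4,
    extend −2); identity is
    the fraction of identical columns over the full alignment length, in
    [0, 100].  Symmetric, and 100 for a self comparison.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{name} contains non-amino-acid symbols {sorted(bad)}")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / ncols


def enrich_negatives(
    datasets: Mapping[str, TargetDataset],
    sequences: Mapping[str, str],
    config: CurationConfig,
    seed: int = 0,
) -> dict[str, TargetDataset]:
    """Balance each target's inactive set against its active set.

    Targets short of inactives borrow known inactives from other targets in
    descending order of sequence identity (ties broken by target id), never
    from donors below ``similarity_floor_pct`` identity, and never borrowing a
    compound the recipient already holds.  If eligible donors run out, the
    dataset keeps a ``shortfall`` flag.  Targets with excess inactives are
    down-sampled to balance using ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, TargetDataset] = {}
    for tid in sorted(datasets):
        ds = datasets[tid]
        n_act, n_inact = len(ds.actives), len(ds.inactives)
        new = TargetDataset(
            tid,
            dict(ds.actives),
            dict(ds.inactives),
            list(ds.enrichment_provenance),
            ds.shortfall,
        )
        if n_inact > n_act:
            keep = rng.choice(sorted(new.inactives), size=n_act, replace=False)
            new.inactives = {cid: new.inactives[cid] for cid in sorted(keep)}
        elif n_inact < n_act:
            if tid not in sequences:
                raise KeyError(f"no sequence available for target {tid!r} needing enrichment")
            donors: list[tuple[float, str]] = []
            for other in sorted(datasets):
                if other == tid or other not in sequences:
                    continue
                ident = pairwise_sequence_identity(sequences[tid], sequences[other])
                if ident >= config.similarity_floor_pct:
                    donors.append((ident, other))
            donors.sort(key=lambda d: (-d[0], d[1]))
            need = n_act - n_inact
            for ident, donor in donors:
                if need == 0:
                    break
                for cid in sorted(datasets[donor].inactives):
                    if need == 0:
                        break
                    if cid in new.actives or cid in new.inactives:
                        continue
                    new.inactives[cid] = datasets[donor].inactives[cid]
                    new.enrichment_provenance.append((cid, donor, ident))
                    need -= 1
            if need > 0:
                new.shortfall = True
        new.check_invariants()
        out[tid] = new
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline with a stage-count report


def _drop_unparseable_smiles(
    records: Sequence[BioactivityRecord], config: CurationConfig
) -> tuple[list[BioactivityRecord], int]:
    """Fail-soft SMILES validation, with optional largest-fragment keeping."""
    from rdkit import Chem

    kept: list[BioactivityRecord] = []
    dropped = 0
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("dropping record %s: unparseable SMILES %r", rec.compound_id, rec.smiles)
            dropped += 1
            continue
        if config.strip_salts and "." in rec.smiles:
            frags = Chem.GetMolFrags(mol, asMols=True)
            largest = max(frags, key=lambda f: f.GetNumAtoms())
            rec = replace(rec, smiles=Chem.MolToSmiles(largest))
        kept.append(rec)
    return kept, dropped


def curate(
    records: Sequence[BioactivityRecord],
    config: CurationConfig | None = None,
    sequences: Mapping[str, str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, TargetDataset], dict]:
    """Run the full curation pipeline; return modelled datasets and a report.

    The report records the number of records surviving each stage, so runs on
    generated tables can be audited against known ground truth.
    """
    config = config or CurationConfig()
    report: dict = {"n_input": len(records)}

    stagewise, n_bad_smiles = _drop_unparseable_smiles(records, config)
    report["n_unparseable_smiles"] = n_bad_smiles
    for stage, cfg in (
        ("target_type", replace(config, allowed_taxa=None, allowed_assay_types=frozenset(ASSAY_TYPES), allowed_standard_types=frozenset(STANDARD_TYPES), require_pchembl=False)),
        ("taxon", replace(config, allowed_assay_types=frozenset(ASSAY_TYPES), allowed_standard_types=frozenset(STANDARD_TYPES), require_pchembl=False)),
        ("assay_type", replace(config, allowed_standard_types=frozenset(STANDARD_TYPES), require_pchembl=False)),
        ("standard_type", replace(config, require_pchembl=False)),
        ("pchembl", config),
    ):
        stagewise = filter_records(stagewise, cfg)
        report[f"after_{stage}"] = len(stagewise)

    deduped = aggregate_duplicates(stagewise)
    report["after_aggregation"] = len(deduped)

    labelled = label_by_threshold(deduped, config)
    report["n_active"] = sum(len(ds.actives) for ds in labelled.values())
    report["n_inactive"] = sum(len(ds.inactives) for ds in labelled.values())
    report["n_gray_zone"] = report["after_aggregation"] - sum(
        len(ds.actives) + len(ds.inactives) for ds in labelled.values()
    )

    modelled = select_modelled_targets(labelled, config)
    report["modelled_targets"] = modelled
    selected = {t: labelled[t] for t in modelled}

    if sequences is not None:
        selected = enrich_negatives(selected, sequences, config, seed=seed)
        report["enriched_inactives"] = sum(
            len(ds.enrichment_provenance) for ds in selected.values()
        )
    return selected, report


# ---------------------------------------------------------------------------
# I/O

#: mapping from ChEMBL export column names to BioactivityRecord fields
CHEMBL_COLUMN_MAP = {
    "molecule_chembl_id": "compound_id",
    "canonical_smiles": "smiles",
    "target_chembl_id": "target_id",
    "target_type": "target_type",
    "organism": "taxon",
    "assay_type": "assay_type",
    "standard_type": "standard_type",
    "standard_relation": "standard_relation",
    "standard_value": "standard_value_nm",
    "pchembl_value": "pchembl",
    "document_year": "doc_year",
}


def read_bioactivity_table(path: str | Path) -> list[BioactivityRecord]:
    """Read a CSV/TSV bioactivity table (native or ChEMBL column names)."""
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    records: list[BioactivityRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        for row in reader:
            kv = {}
            for col, value in row.items():
                name = CHEMBL_COLUMN_MAP.get(col, col)
                if name not in BioactivityRecord.__dataclass_fields__:
                    continue
                kv[name] = value
            rec = BioactivityRecord(
                compound_id=kv["compound_id"],
                smiles=kv["smiles"],
                target_id=kv["target_id"],
                target_type=kv.get("target_type") or "single_protein",
                taxon=kv.get("taxon") or "Homo sapiens",
                assay_type=kv.get("assay_type") or "binding",
                standard_type=kv.get("standard_type") or "IC50",
                standard_relation=kv.get("standard_relation") or "=",
                standard_value_nm=float(kv["standard_value_nm"]),
                pchembl=float(kv["pchembl"]) if kv.get("pchembl") else None,
                doc_year=int(kv["doc_year"]) if kv.get("doc_year") else None,
            )
            records.append(rec)
    return records


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read target protein sequences keyed by FASTA record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_target_datasets(
    datasets: Mapping[str, TargetDataset], report: dict, out_dir: str | Path
) -> None:
    """Write one labelled CSV per target plus a JSON curation report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tid, ds in datasets.items():
        with open(out / f"{tid}.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["compound_id", "smiles", "label", "donor_target", "donor_identity"])
            prov = {cid: (donor, ident) for cid, donor, ident in ds.enrichment_provenance}
            for cid in sorted(ds.actives):
                writer.writerow([cid, ds.actives[cid], "active", "", ""])
            for cid in sorted(ds.inactives):
                donor, ident = prov.get(cid, ("", ""))
                writer.writerow([cid, ds.inactives[cid], "inactive", donor, ident])
    with open(out / "curation_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
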