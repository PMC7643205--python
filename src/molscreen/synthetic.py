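"""Synthetic test inputs with known ground truth.

Three generators emulate the external data every other module consumes, so
the whole toolkit can be built and exercised offline:

* :func:`generate_smiles_library` — molecule libraries with a planted
  activity-defining substructure.  Actives are guaranteed (and verified by
  substructure match) to contain the planted group; inactives are built from
  a fragment alphabet that cannot produce it.  Optional label noise is
  applied after generation and recorded in the manifest.
* :func:`generate_bioactivity_table` — ChEMBL-style bioactivity tables with
  controlled mixtures of filter defects, duplicate measurements and
  gray-zone values; the companion manifest states the expected survivor
  count of every curation stage, computed from the construction plan alone.
* :func:`generate_target_sequences` — protein sequence sets with controlled
  percent identity to a reference sequence (star topology), for exercising
  similarity-ordered negative enrichment.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .curation import BioactivityRecord, CurationConfig

# sulfur-free building blocks, so the default planted group (a sulfonamide)
# can never arise in an inactive by accident
SCAFFOLD_POOL: tuple[str, ...] = (
    "c1ccccc1",
    "c1ccncc1",
    "c1cncnc1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOCC1",
    "c1ccc2ccccc2c1",
    "c1ccoc1",
    "C1CCCC1",
    "c1cc2ccccc2[nH]1",
)
FRAGMENT_ALPHABET: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCO", "CO", "N", "NC", "O", "OC", "F", "Cl", "Br", "C=C", "C(=O)O",
)
DEFAULT_PLANTED = "S(=O)(=O)N"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a planted-SAR molecule library."""

    n_actives: int = 100
    n_inactives: int = 100
    planted_substructure: str = DEFAULT_PLANTED
    scaffold_pool_size: int = 6
    fragment_pool_size: int = len(FRAGMENT_ALPHABET)
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise rate must be in [0, 1]")
        if Chem.MolFromSmarts(self.planted_substructure) is None:
            raise ValueError(f"planted substructure {self.planted_substructure!r} unparseable")
        if not 1 <= self.scaffold_pool_size <= len(SCAFFOLD_POOL):
            raise ValueError("scaffold_pool_size out of range")
        if not 1 <= self.fragment_pool_size <= len(FRAGMENT_ALPHABET):
            raise ValueError("fragment_pool_size out of range")


def _attach(core: Chem.Mol, fragment_smiles: str, rng: np.random.Generator) -> Chem.Mol | None:
    """Bond a fragment's first atom to a random substitutable core atom."""
    frag = Chem.MolFromSmiles(fragment_smiles)
    if frag is None:
        return None
    sites = [
        a.GetIdx()
        for a in core.GetAtoms()
        if a.GetTotalNumHs() >= 1 and a.GetSymbol() in ("C", "N")
    ]
    if not sites:
        return None
    site = int(rng.choice(sites))
    combined = Chem.RWMol(Chem.CombineMols(core, frag))
    combined.AddBond(site, core.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _build_molecule(
    scaffolds: Sequence[str],
    fragments: Sequence[str],
    rng: np.random.Generator,
    planted: str | None,
) -> str | None:
    core = Chem.MolFromSmiles(str(rng.choice(list(scaffolds))))
    n_sub = int(rng.integers(1, 4))
    for _ in range(n_sub):
        frag = str(rng.choice(list(fragments)))
        nxt = _attach(core, frag, rng)
        if nxt is not None:
            core = nxt
    if planted is not None:
        core = _attach(core, planted, rng)
        if core is None:
            return None
    return Chem.MolToSmiles(core)


def generate_smiles_library(
    spec: FixtureSpec,
) -> tuple[list[tuple[str, str, str]], dict]:
    """Generate a labelled molecule library with a planted active motif.

    Returns ``(entries, manifest)`` where each entry is
    ``(smiles, compound_id, label)``.  Pre-noise, every active matches the
    planted substructure and no inactive does (both verified); labels are
    then flipped at ``noise_rate``, and the flipped ids are recorded in the
    manifest.  Raises if the scaffold/fragment pool cannot yield enough
    unique molecules.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x11B]))
    scaffolds = SCAFFOLD_POOL[: spec.scaffold_pool_size]
    fragments = FRAGMENT_ALPHABET[: spec.fragment_pool_size]
    pattern = Chem.MolFromSmarts(spec.planted_substructure)

    seen: set[str] = set()
    entries: list[tuple[str, str, str]] = []

    for label, count, planted in (
        ("active", spec.n_actives, spec.planted_substructure),
        ("inactive", spec.n_inactives, None),
    ):
        made = 0
        stalled = 0
        while made < count:
            stalled += 1
            if stalled > 2000:  # no new unique molecule in many attempts: pool exhausted
                raise ValueError(
                    f"infeasible spec: pool exhausted at {made}/{count} unique "
                    f"{label} molecules"
                )
            smiles = _build_molecule(scaffolds, fragments, rng, planted)
            if smiles is None or smiles in seen:
                continue
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            matches = mol.HasSubstructMatch(pattern)
            if (label == "active") != matches:
                continue
            seen.add(smiles)
            prefix = "A" if label == "active" else "I"
            entries.append((smiles, f"{prefix}{made:05d}", label))
            made += 1
            stalled = 0

    flipped: list[str] = []
    if spec.noise_rate > 0:
        n_flip = int(round(spec.noise_rate * len(entries)))
        idx = rng.choice(len(entries), size=n_flip, replace=False)
        for i in sorted(int(j) for j in idx):
            smiles, cid, label = entries[i]
            entries[i] = (smiles, cid, "inactive" if label == "active" else "active")
            flipped.append(cid)

    manifest = {
        "n_actives": spec.n_actives,
        "n_inactives": spec.n_inactives,
        "planted_substructure": spec.planted_substructure,
        "noise_rate": spec.noise_rate,
        "flipped_ids": flipped,
        "seed": spec.seed,
    }
    return entries, manifest


# ---------------------------------------------------------------------------
# bioactivity tables


@dataclass(frozen=True)
class TableSpec:
    """Per-target record mixture for a synthetic bioactivity table."""

    targets: tuple[str, ...] = ("T1", "T2")
    n_active: int = 10
    n_inactive: int = 10
    n_gray: int = 3
    n_bad_target_type: int = 2
    n_bad_taxon: int = 2
    n_bad_assay: int = 2
    n_bad_standard_type: int = 2
    n_missing_pchembl: int = 2
    n_duplicate_triples: int = 2  # triples of replicate measurements, active zone
    seed: int = 0


_SMILES_POOL = ("CCO", "CCN", "CCC", "CCCC", "c1ccccc1", "CC(C)O", "CCOC", "CC(=O)O")


def generate_bioactivity_table(
    spec: TableSpec, config: CurationConfig | None = None
) -> tuple[list[BioactivityRecord], dict]:
    """Emit a bioactivity table plus a manifest of expected survivor counts.

    Every defective record carries exactly one defect, so the manifest's
    per-stage survivor counts follow from the construction plan without ever
    running the curation pipeline (the generator's bookkeeping is the
    oracle).  The supplied config determines the value zones; its taxon
    allow-list must be set whenever taxon-defective records are requested.
    """
    config = config or CurationConfig(allowed_taxa=frozenset({"Homo sapiens"}))
    if spec.n_bad_taxon > 0 and config.allowed_taxa is None:
        raise ValueError("taxon-defective records need a config with an explicit taxon allow-list")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7AB]))
    smiles_cycle = itertools.cycle(_SMILES_POOL)
    records: list[BioactivityRecord] = []
    counter = itertools.count()

    def base_kwargs(target: str, value: float) -> dict:
        taxon = "Homo sapiens"
        if config.allowed_taxa is not None:
            taxon = sorted(config.allowed_taxa)[0]
        return dict(
            compound_id=f"C{next(counter):06d}",
            smiles=next(smiles_cycle),
            target_id=target,
            target_type=sorted(config.allowed_target_types)[0],
            taxon=taxon,
            assay_type=sorted(config.allowed_assay_types)[0],
            standard_type=sorted(config.allowed_standard_types)[0],
            standard_relation="=",
            standard_value_nm=value,
            pchembl=5.0,
            doc_year=int(rng.integers(2005, 2020)),
        )

    def active_value() -> float:
        return float(rng.integers(1, int(config.active_threshold_nm)))

    def inactive_value() -> float:
        return float(rng.integers(int(config.inactive_threshold_nm), int(config.inactive_threshold_nm * 10)))

    def gray_value() -> float:
        lo, hi = config.active_threshold_nm, config.inactive_threshold_nm
        return float(lo + 1 + rng.integers(0, int(hi - lo - 2)))

    for target in spec.targets:
        for _ in range(spec.n_active):
            records.append(BioactivityRecord(**base_kwargs(target, active_value())))
        for _ in range(spec.n_inactive):
            records.append(BioactivityRecord(**base_kwargs(target, inactive_value())))
        for _ in range(spec.n_gray):
            records.append(BioactivityRecord(**base_kwargs(target, gray_value())))
        for _ in range(spec.n_bad_target_type):
            records.append(BioactivityRecord(**{**base_kwargs(target, active_value()), "target_type": "other"}))
        for _ in range(spec.n_bad_taxon):
            records.append(BioactivityRecord(**{**base_kwargs(target, active_value()), "taxon": "Danio rerio"}))
        for _ in range(spec.n_bad_assay):
            records.append(BioactivityRecord(**{**base_kwargs(target, active_value()), "assay_type": "functional"}))
        for _ in range(spec.n_bad_standard_type):
            records.append(BioactivityRecord(**{**base_kwargs(target, active_value()), "standard_type": "other"}))
        for _ in range(spec.n_missing_pchembl):
            records.append(BioactivityRecord(**{**base_kwargs(target, active_value()), "pchembl": None}))
        for _ in range(spec.n_duplicate_triples):
            kw = base_kwargs(target, 0.0)
            v = sorted(float(x) for x in rng.integers(1, int(config.active_threshold_nm), size=3))
            for val in v:
                records.append(BioactivityRecord(**{**kw, "standard_value_nm": val}))

    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    n_targets = len(spec.targets)
    per_target_conforming = (
        spec.n_active + spec.n_inactive + spec.n_gray + 3 * spec.n_duplicate_triples
    )
    n_input = n_targets * (
        per_target_conforming
        + spec.n_bad_target_type
        + spec.n_bad_taxon
        + spec.n_bad_assay
        + spec.n_bad_standard_type
        + spec.n_missing_pchembl
    )
    survivors = n_input
    manifest: dict = {"n_input": n_input}
    for stage, bad in (
        ("target_type", spec.n_bad_target_type),
        ("taxon", spec.n_bad_taxon),
        ("assay_type", spec.n_bad_assay),
        ("standard_type", spec.n_bad_standard_type),
        ("pchembl", spec.n_missing_pchembl),
    ):
        survivors -= n_targets * bad
        manifest[f"after_{stage}"] = survivors
    manifest["after_aggregation"] = survivors - n_targets * 2 * spec.n_duplicate_triples
    # duplicate triples lie entirely in the active zone, so their medians are active
    manifest["n_active"] = n_targets * (spec.n_active + spec.n_duplicate_triples)
    manifest["n_inactive"] = n_targets * spec.n_inactive
    manifest["n_gray_zone"] = n_targets * spec.n_gray
    manifest["modelled_targets"] = sorted(
        spec.targets
    ) if spec.n_active + spec.n_duplicate_triples >= config.min_actives else []
    manifest["seed"] = spec.seed
    return records, manifest


# ---------------------------------------------------------------------------
# protein sequences

_AA = "ACDEFGHIKLMNPQRSTVWY"


def generate_target_sequences(
    identities: Mapping[str, float], seed: int = 0, length: int = 150
) -> dict[str, str]:
    """Sequences at requested percent identity to a common reference.

    The first mapping entry at 100% identity is the reference itself; every
    other sequence is a copy of the reference with the complementary
    fraction of positions substituted (star topology), so its realized
    identity to the reference matches the request to within rounding.
    Requests outside [0, 100] are infeasible and rejected.
    """
    for tid, ident in identities.items():
        if not 0.0 <= ident <= 100.0:
            raise ValueError(f"infeasible identity {ident} for target {tid!r}")
    if length < 10:
        raise ValueError("sequence length must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E0]))
    base = "".join(rng.choice(list(_AA), size=length))
    out: dict[str, str] = {}
    for tid in identities:
        ident = identities[tid]
        n_mut = int(round((1.0 - ident / 100.0) * length))
        seq = list(base)
        positions = rng.choice(length, size=n_mut, replace=False)
        for pos in positions:
            current = seq[pos]
            choices = [a for a in _AA if a != current]
            seq[pos] = str(rng.choice(choices))
        out[tid] = "".join(seq)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sequences:
            fh.write(f">{tid}\n{sequences[tid]}\n")
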