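"""Molecular representations: 2-D images, circular fingerprints, scaffolds.

The image featurization draws the skeletal formula of a molecule onto a
square single-channel pixel grid.  Rendering is fully deterministic: the
input SMILES is canonicalized (stereochemistry stripped), 2-D coordinates are
computed from the canonical atom order, and the depiction is rasterized with
a pinned style — anti-aliased bond lines, parallel offset lines for multiple
bonds, and heteroatoms drawn as filled disks whose radius scales with the
element's covalent size.  Two SMILES spellings of the same molecule therefore
produce bit-identical grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image
from rdkit import Chem, RDLogger
from rdkit.Chem import rdDepictor, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from skimage.draw import disk, line_aa

RDLogger.DisableLog("rdApp.*")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonical_smiles(smiles: str, strip_stereo: bool = True) -> str:
    """Canonical SMILES; stereochemistry is stripped by default."""
    mol = _mol_from_smiles(smiles)
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# 2-D image rendering

#: pinned depiction style — part of the deterministic rendering contract
_MARGIN_FRACTION = 0.08
#: maximum pixels per coordinate unit, so single atoms are not blown up
_MAX_SCALE_FRACTION = 1 / 8
#: perpendicular offset between parallel lines of multiple bonds (coord units)
_MULTIBOND_OFFSET = 0.18
#: base heteroatom disk radius as a fraction of image side
_ATOM_RADIUS_FRACTION = 0.012
#: relative disk size per element (roughly covalent radius ordering)
_ELEMENT_SIZE = {
    "B": 0.9, "N": 1.0, "O": 1.0, "F": 0.8, "Si": 1.3, "P": 1.3, "S": 1.3,
    "Cl": 1.2, "Se": 1.4, "Br": 1.5, "I": 1.8,
}


@dataclass(frozen=True)
class MoleculeImage:
    """A square single-channel raster of a molecule (1 = ink, 0 = background)."""

    pixels: np.ndarray
    size: int
    source_smiles: str

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.size, self.size):
            raise ValueError("pixel grid is not square with the declared side")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values outside [0, 1]")

    def to_png(self, path: str | Path) -> None:
        """Export as a grayscale PNG (dark ink on white background)."""
        arr = np.round(255 * (1.0 - self.pixels)).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(str(path))

    def as_channels(self, n_channels: int = 1) -> np.ndarray:
        """The grid replicated to ``(n_channels, S, S)`` for RGB-style consumers."""
        if n_channels < 1:
            raise ValueError("need at least one channel")
        return np.repeat(self.pixels[None, :, :], n_channels, axis=0)


def _draw_line(grid: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> None:
    size = grid.shape[0]
    rr, cc, val = line_aa(
        int(round(p0[0])), int(round(p0[1])), int(round(p1[0])), int(round(p1[1]))
    )
    keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
    rr, cc, val = rr[keep], cc[keep], val[keep]
    np.maximum.at(grid, (rr, cc), val.astype(np.float32))


def render_molecule_image(smiles: str, size: int = 200) -> MoleculeImage:
    """Render a molecule's skeletal formula to a ``size`` x ``size`` grid.

    Deterministic: identical molecules (after canonicalization) give
    bit-identical grids at a given size.  Any molecule with at least one atom
    produces non-zero ink.  For consumers that expect multi-channel input,
    :meth:`MoleculeImage.as_channels` replicates the grid.

    Parameters
    ----------
    smiles:
        Input structure.  Stereochemistry is ignored.
    size:
        Image side in pixels; at least 64 (100, 200 and 400 are the sizes
        studied for this featurization; 200 is the default).
    """
    if size < 64:
        raise ValueError(f"image size must be >= 64, got {size}")
    canon = canonical_smiles(smiles)
    mol = _mol_from_smiles(canon)
    rdDepictor.Compute2DCoords(mol)
    conf = mol.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y] for i in range(mol.GetNumAtoms())]
    )

    # map coordinates into the pixel grid with a fixed margin, preserving aspect
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = float(max(hi[0] - lo[0], hi[1] - lo[1]))
    usable = size * (1 - 2 * _MARGIN_FRACTION)
    scale = min(usable / span if span > 0 else np.inf, size * _MAX_SCALE_FRACTION)
    center = (lo + hi) / 2.0
    # x -> column, y -> row (flipped so +y points up)
    cols = (coords[:, 0] - center[0]) * scale + size / 2.0
    rows = size / 2.0 - (coords[:, 1] - center[1]) * scale
    pix = np.stack([rows, cols], axis=1)

    grid = np.zeros((size, size), dtype=np.float32)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        p0, p1 = pix[a], pix[b]
        order = bond.GetBondType()
        nlines = {Chem.BondType.DOUBLE: 2, Chem.BondType.TRIPLE: 3}.get(order, 1)
        direction = p1 - p0
        norm = np.linalg.norm(direction)
        perp = (
            np.array([-direction[1], direction[0]]) / norm
            if norm > 0
            else np.array([0.0, 0.0])
        )
        offsets = {1: [0.0], 2: [-0.5, 0.5], 3: [-1.0, 0.0, 1.0]}[nlines]
        for k in offsets:
            shift = perp * k * _MULTIBOND_OFFSET * scale
            _draw_line(grid, p0 + shift, p1 + shift)

    base_radius = max(2.0, size * _ATOM_RADIUS_FRACTION)
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol == "C":
            continue  # skeletal formula: carbons are implicit
        radius = base_radius * _ELEMENT_SIZE.get(symbol, 1.1)
        rr, cc = disk((pix[atom.GetIdx()][0], pix[atom.GetIdx()][1]), radius, shape=grid.shape)
        grid[rr, cc] = 1.0

    if mol.GetNumAtoms() == 1:  # single atom, no bonds: draw it even if carbon
        rr, cc = disk((pix[0][0], pix[0][1]), base_radius, shape=grid.shape)
        grid[rr, cc] = 1.0

    return MoleculeImage(pixels=grid, size=size, source_smiles=canon)


# ---------------------------------------------------------------------------
# fingerprints and similarity


@dataclass(frozen=True)
class Fingerprint:
    """Circular (Morgan) fingerprint as a set of on-bits over a fixed width."""

    bits: frozenset[int]
    width: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.width:
            raise ValueError("bit index exceeds fingerprint width")


def ecfp(smiles: str, radius: int = 2, width: int = 2048) -> Fingerprint:
    """Morgan/ECFP fingerprint (radius 2 and width 2048 give ECFP4)."""
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), width=width, radius=radius)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B|; 1.0 when both bit sets are empty."""
    if fp_a.width != fp_b.width:
        raise ValueError(f"fingerprint width mismatch: {fp_a.width} vs {fp_b.width}")
    union = len(fp_a.bits | fp_b.bits)
    if union == 0:
        return 1.0
    return len(fp_a.bits & fp_b.bits) / union


# ---------------------------------------------------------------------------
# scaffolds


@dataclass(frozen=True)
class ScaffoldKey:
    """Canonical SMILES of a molecule's Murcko scaffold.

    ``generalized`` scaffolds additionally collapse atom types and bond
    orders to a generic framework.  Acyclic molecules have the empty key.
    """

    smiles: str
    generalized: bool = False


def murcko_scaffold(smiles: str, generalized: bool = False) -> ScaffoldKey:
    """Murcko scaffold (ring systems plus linkers, side chains removed)."""
    mol = _mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ScaffoldKey("", generalized)
    if generalized:
        scaffold = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    return ScaffoldKey(Chem.MolToSmiles(scaffold), generalized)


# ---------------------------------------------------------------------------
# .smi I/O


def read_smi(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi file ("SMILES<TAB>ID" per line) as (smiles, id) pairs."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smiles = parts[0]
            ident = parts[1] if len(parts) > 1 else smiles
            out.append((smiles, ident))
    return out


def write_smi(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for smiles, ident in entries:
            fh.write(f"{smiles}\t{ident}\n")
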