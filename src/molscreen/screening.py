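"""Batch library screening and the scalar conversions used alongside it.

``screen_library`` runs any number of trained per-target models over a
SMILES library in constant memory per batch, emitting either every scored
(model, compound) pair or only the active calls.  The conversions relate a
docking free energy to a dissociation constant (Kd = exp(dG/RT)) and a
pChEMBL value to a nanomolar concentration (10^(9 - pChEMBL)).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from . import cnn
from .features import SmilesParseError, render_molecule_image

logger = logging.getLogger(__name__)

#: RT in kcal/mol at ~297 K — the single value consistent with standard
#: docking-report dG/Kd conversions near room temperature
DEFAULT_RT_KCAL_MOL = 0.5905
#: RT at the thermodynamic standard 298.15 K, for callers who prefer it
RT_298K_KCAL_MOL = 0.59248


def dg_to_kd(dg_kcal_mol: float, rt_kcal_mol: float = DEFAULT_RT_KCAL_MOL) -> float:
    """Dissociation constant (molar) from a binding free energy (kcal/mol).

    Kd = exp(dG/RT); negative dG (favorable binding) gives Kd < 1 M.
    """
    if rt_kcal_mol <= 0:
        raise ValueError("RT must be positive")
    return math.exp(dg_kcal_mol / rt_kcal_mol)


def pchembl_to_nm(pchembl: float) -> float:
    """Concentration in nM equivalent to a pChEMBL (-log10 molar) value."""
    return 10.0 ** (9.0 - pchembl)


def nm_to_pchembl(value_nm: float) -> float:
    if value_nm <= 0:
        raise ValueError("concentration must be positive")
    return 9.0 - math.log10(value_nm)


def round_to_sig_figs(value: float, n_figs: int) -> float:
    """Round a positive value to ``n_figs`` significant figures."""
    if value <= 0:
        raise ValueError("value must be positive")
    exponent = math.floor(math.log10(value))
    return round(value, -exponent + n_figs - 1)


@dataclass(frozen=True)
class ScreeningResult:
    compound_id: str
    target_id: str
    probability: float
    call: str  # active | inactive
    model_hash: str


def _model_hash(model: "cnn.TrainedModel") -> str:
    h = hashlib.sha256()
    h.update(json.dumps(model.manifest, sort_keys=True, default=str).encode())
    return h.hexdigest()[:12]


def screen_library(
    models: Mapping[str, "cnn.TrainedModel"],
    library: Iterable[tuple[str, str]],
    threshold: float = 0.5,
    emit: str = "all",
    batch_size: int = 64,
) -> list[ScreeningResult]:
    """Score every (model, compound) pair over a (smiles, id) library.

    Unparseable library entries are logged and skipped.  ``emit="all"``
    returns every scored pair; ``emit="actives_only"`` keeps calls with
    probability >= threshold.  The library is consumed in batches so memory
    use is bounded by the batch size, not the library size.
    """
    if not models:
        raise ValueError("no models supplied")
    if emit not in ("all", "actives_only"):
        raise ValueError(f"unknown emit mode {emit!r}")

    sizes = {m.image_size for m in models.values()}
    hashes = {tid: _model_hash(m) for tid, m in models.items()}
    results: list[ScreeningResult] = []

    def batches() -> Iterator[list[tuple[str, str]]]:
        batch: list[tuple[str, str]] = []
        for entry in library:
            batch.append(entry)
            if len(batch) >= batch_size:
                yield batch
                batch = []
        if batch:
            yield batch

    for batch in batches():
        rendered: dict[int, dict[str, object]] = {}
        parseable: list[tuple[str, str]] = []
        for smiles, cid in batch:
            try:
                imgs = {size: render_molecule_image(smiles, size) for size in sizes}
            except SmilesParseError:
                logger.warning("screening: skipped unparseable SMILES %r (%s)", smiles, cid)
                continue
            rendered[len(parseable)] = imgs
            parseable.append((smiles, cid))
        if not parseable:
            continue
        for tid in sorted(models):
            model = models[tid]
            images = [rendered[i][model.image_size] for i in range(len(parseable))]
            probs = cnn.predict_proba(model, images)
            for (smiles, cid), prob in zip(parseable, probs):
                call = "active" if prob >= threshold else "inactive"
                if emit == "actives_only" and call != "active":
                    continue
                results.append(ScreeningResult(cid, tid, float(prob), call, hashes[tid]))
    return results


def write_screening_tsv(results: Sequence[ScreeningResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["compound_id", "target_id", "probability", "call", "model_hash"])
        for r in results:
            writer.writerow([r.compound_id, r.target_id, f"{r.probability:.6f}", r.call, r.model_hash])
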