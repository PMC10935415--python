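"""Fragment-library screening for candidate zinc-binding fragments.

The screen is a two-stage AND filter: a molecule must first be predicted
highly active by the trained classifier, and must then fall inside the
electronic-descriptor gate — the closed interval mu +/- 1.96 sigma per
gated descriptor, where mu and sigma are taken over the reference
population of high-activity ligands. Candidate metalloenzyme inhibitors
are then found by a substructure search against a curated table of
zinc-binding fragment (ZnBF) SMARTS patterns; the shipped table encodes
the classic fragments (hydroxamic acid, sulfonamide, urea, phosphonate,
carboxylate, ...) with their metal-coordinating atoms annotated, and
best-effort synthetic encodings for the remainder (flagged in the file).

For 3D complexes, :func:`extract_binding_atoms` applies the geometric
rule used to annotate coordinating atoms: O/N/S/F heteroatoms within
2.8 Angstrom of the metal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem

from .classifiers import _as_matrix  # shared column-alignment helper
from .evaluation import POSITIVE_CLASS

__all__ = [
    "ZnbfPattern",
    "MetalSite",
    "ScreenHit",
    "ScreeningError",
    "load_znbf_patterns",
    "build_gate",
    "screen_library",
    "substructure_search",
    "inhibitor_search",
    "rank_hits",
    "extract_binding_atoms",
    "GATE_MULTIPLIER",
]

GATE_MULTIPLIER = 1.96
BINDING_CUTOFF = 2.8  # Angstrom
BINDING_ELEMENTS = frozenset({"O", "N", "S", "F"})


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class ZnbfPattern:
    """A zinc-binding fragment as a SMARTS pattern with annotated donors."""

    id: str
    smarts: str
    binding_atom_indices: tuple[int, ...]
    denticity: str  # monodentate | bidentate
    provenance: str  # known | synthetic | discovered

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:  # pragma: no cover - validated at load
            raise ScreeningError(f"pattern {self.id}: invalid SMARTS")
        return q


def load_znbf_patterns(path: str | Path | None = None) -> list[ZnbfPattern]:
    """Load and validate the ZnBF pattern table (CSV).

    Defaults to the packaged table. Rejects unparseable SMARTS, out-of-range
    binding atom indices, and binding atoms that are not O/N/S/F (generic
    query atoms whose element is an O/N/S/F alternation are accepted).
    """
    if path is None:
        src = resources.files("zincscreen").joinpath("data/znbf_patterns.csv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    patterns: list[ZnbfPattern] = []
    for row in csv.DictReader(text.splitlines()):
        q = Chem.MolFromSmarts(row["smarts"])
        if q is None:
            raise ScreeningError(f"pattern {row['id']}: invalid SMARTS {row['smarts']!r}")
        idx = tuple(int(i) for i in str(row["binding_atom_indices"]).split(";"))
        for i in idx:
            if not 0 <= i < q.GetNumAtoms():
                raise ScreeningError(f"pattern {row['id']}: binding atom {i} out of range")
            num = q.GetAtomWithIdx(i).GetAtomicNum()
            # 0 = composite query atom (e.g. an O-or-O-anion alternation)
            if num not in (0, 7, 8, 9, 16):
                raise ScreeningError(
                    f"pattern {row['id']}: binding atom {i} is not O/N/S/F"
                )
        patterns.append(
            ZnbfPattern(
                id=row["id"],
                smarts=row["smarts"],
                binding_atom_indices=idx,
                denticity=row["denticity"],
                provenance=row["provenance"],
            )
        )
    if not patterns:
        raise ScreeningError("empty pattern table")
    return patterns


def build_gate(
    profiles: pd.DataFrame,
    gated_names: list[str] | None = None,
    multiplier: float = GATE_MULTIPLIER,
) -> dict[str, tuple[float, float]]:
    """Per-descriptor closed intervals [mu - m*sigma, mu + m*sigma].

    ``profiles`` is the output of
    :func:`zincscreen.descriptors.profile_descriptors` (indexed by
    descriptor name, with ``mean``/``sd`` over the reference population).
    The default gated set is every descriptor flagged electronic. A zero
    sigma yields the degenerate interval [mu, mu].
    """
    if gated_names is None:
        gated_names = [str(n) for n in profiles.index[profiles["is_electronic"]]]
    missing = [n for n in gated_names if n not in profiles.index]
    if missing:
        raise ScreeningError(f"gated descriptors absent from profiles: {missing}")
    gate = {}
    for name in gated_names:
        mu = float(profiles.loc[name, "mean"])
        sd = float(profiles.loc[name, "sd"])
        gate[name] = (mu - multiplier * sd, mu + multiplier * sd)
    return gate


@dataclass
class ScreenHit:
    """Per-molecule outcome of the prediction + gate screen."""

    molecule_id: str
    predicted_class: str
    model_score: float
    gate_results: dict[str, dict] = field(default_factory=dict)
    matched_patterns: list[str] = field(default_factory=list)
    overall_pass: bool = False


def screen_library(
    descriptors: pd.DataFrame,
    model,
    gate: dict[str, tuple[float, float]],
    feature_names: list[str] | None = None,
) -> list[ScreenHit]:
    """Two-stage screen: classifier prediction AND descriptor gate.

    Every library molecule is reported with its per-stage outcomes;
    ``overall_pass`` is true iff the model predicts the high-activity class
    and every gated descriptor value lies inside its closed interval.
    Molecules lacking a gated descriptor fail the gate with a recorded
    reason.
    """
    feats = feature_names or [str(n) for n in getattr(model, "feature_names_in_", [])]
    if feats:
        missing = [f for f in feats if f not in descriptors.columns]
        if missing:
            raise ScreeningError(f"library lacks model features: {missing}")
        X = descriptors[feats]
    else:
        X = descriptors
    predictions = model.predict(X)
    idx = int(np.flatnonzero(model.classes_ == POSITIVE_CLASS)[0])
    scores = model.predict_proba(X)[:, idx]

    hits: list[ScreenHit] = []
    for i, mid in enumerate(descriptors.index):
        gate_results: dict[str, dict] = {}
        gate_pass = True
        for name, (lo, hi) in gate.items():
            if name not in descriptors.columns or pd.isna(descriptors.loc[mid, name]):
                gate_results[name] = {
                    "value": None, "lower": lo, "upper": hi,
                    "pass": False, "reason": "descriptor missing",
                }
                gate_pass = False
                continue
            v = float(descriptors.loc[mid, name])
            ok = lo <= v <= hi
            gate_results[name] = {"value": v, "lower": lo, "upper": hi, "pass": bool(ok)}
            gate_pass = gate_pass and ok
        predicted = str(predictions[i])
        hits.append(
            ScreenHit(
                molecule_id=str(mid),
                predicted_class=predicted,
                model_score=float(scores[i]),
                gate_results=gate_results,
                overall_pass=bool(predicted == POSITIVE_CLASS and gate_pass),
            )
        )
    return hits


def substructure_search(
    structures: dict[str, str], patterns: list[ZnbfPattern]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """SMARTS substructure search of a library against ZnBF patterns.

    Returns a hit table (one row per molecule with >= 1 matching pattern,
    listing matched pattern ids and matched atom indices) and per-pattern
    hit counts. Unparseable library SMILES are skipped.
    """
    queries = [(p, p.query()) for p in patterns]
    rows = []
    per_pattern = {p.id: 0 for p in patterns}
    for mid in sorted(structures):
        mol = Chem.MolFromSmiles(structures[mid])
        if mol is None:
            continue
        matched_ids, matched_atoms = [], {}
        for pattern, q in queries:
            matches = mol.GetSubstructMatches(q)
            if matches:
                matched_ids.append(pattern.id)
                matched_atoms[pattern.id] = [list(m) for m in matches]
                per_pattern[pattern.id] += 1
        if matched_ids:
            rows.append(
                {
                    "molecule_id": mid,
                    "smiles": structures[mid],
                    "matched_patterns": matched_ids,
                    "matched_atoms": matched_atoms,
                    "n_patterns": len(matched_ids),
                }
            )
    return pd.DataFrame(rows), per_pattern


def inhibitor_search(
    hits: list[ScreenHit],
    structures: dict[str, str],
    patterns: list[ZnbfPattern],
) -> list[ScreenHit]:
    """Inhibitor-search mode: additionally require a ZnBF substructure.

    Annotates each hit with its matched pattern ids and demotes
    ``overall_pass`` for hits without any ZnBF match.
    """
    table, _ = substructure_search(structures, patterns)
    matched = (
        {r.molecule_id: list(r.matched_patterns) for r in table.itertuples(index=False)}
        if len(table)
        else {}
    )
    out = []
    for h in hits:
        ids = matched.get(h.molecule_id, [])
        out.append(
            ScreenHit(
                molecule_id=h.molecule_id,
                predicted_class=h.predicted_class,
                model_score=h.model_score,
                gate_results=h.gate_results,
                matched_patterns=ids,
                overall_pass=bool(h.overall_pass and ids),
            )
        )
    return out


def rank_hits(hits: list[ScreenHit]) -> list[ScreenHit]:
    """Order passing hits by model score, then matched-pattern count."""
    passing = [h for h in hits if h.overall_pass]
    return sorted(
        passing,
        key=lambda h: (-h.model_score, -len(h.matched_patterns), h.molecule_id),
    )


@dataclass
class MetalSite:
    """One metal atom and the heteroatoms coordinating it."""

    metal_element: str
    metal_coordinates: tuple[float, float, float]
    candidate_atoms: list[dict] = field(default_factory=list)

    @property
    def denticity_by_residue(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.candidate_atoms:
            out[a["residue"]] = out.get(a["residue"], 0) + 1
        return out


def extract_binding_atoms(
    complex_path: str | Path,
    metal_element: str = "Zn",
    cutoff: float = BINDING_CUTOFF,
) -> list[MetalSite]:
    """O/N/S/F atoms within ``cutoff`` Angstrom of each metal atom in a PDB file.

    Returns one :class:`MetalSite` per metal atom, with each candidate's
    element, coordinates, Euclidean distance, and residue/ligand tag.
    Raises when the structure contains no atom of ``metal_element``.
    """
    try:
        structure = gemmi.read_structure(str(complex_path))
    except (RuntimeError, ValueError) as exc:
        raise ScreeningError(f"cannot parse structure {complex_path}: {exc}") from exc
    model = structure[0]

    atoms = []  # (element, pos, tag)
    metals = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                tag = f"{chain.name}/{residue.name}{residue.seqid.num}/{atom.name}"
                el = atom.element.name
                if el.capitalize() == metal_element.capitalize():
                    metals.append((atom.pos, tag))
                atoms.append((el, atom.pos, tag))
    if not metals:
        raise ScreeningError(f"no {metal_element} atom in {complex_path}")

    sites = []
    for mpos, mtag in metals:
        candidates = []
        for el, pos, tag in atoms:
            if el.capitalize() not in BINDING_ELEMENTS:
                continue
            d = float(mpos.dist(pos))
            if d <= cutoff:
                candidates.append(
                    {
                        "element": el.capitalize(),
                        "coordinates": (pos.x, pos.y, pos.z),
                        "distance": d,
                        "residue": tag.rsplit("/", 1)[0],
                        "atom": tag,
                    }
                )
        candidates.sort(key=lambda a: a["distance"])
        sites.append(
            MetalSite(
                metal_element=metal_element,
                metal_coordinates=(mpos.x, mpos.y, mpos.z),
                candidate_atoms=candidates,
            )
        )
    return sites
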