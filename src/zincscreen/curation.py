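"""Dataset curation for zinc-metalloenzyme inhibitor modelling.

Raw activity data arrives as one or more (source, Ki) records per ligand,
typically harvested from different crystal-structure entries of the same
compound. This module merges those records onto the lg(Ki) scale, assigns
high/low activity classes, removes structurally redundant ligands by MACCS
fingerprint similarity, and produces the modeling / external-test /
train / internal-test splits used downstream.

Conventions
-----------
* Ki is in nanomolar; lg(Ki) is its decadic logarithm.
* ``high`` activity means lg(Ki) < 2, ``low`` means lg(Ki) > 3; ligands
  with merged lg(Ki) in the closed interval [2, 3] are excluded from
  modelling.
* Replicate Ki records for one ligand are averaged on the log scale when
  their spread (max - min of lg(Ki)) is at most 1 log unit, and the ligand
  is discarded entirely when the spread exceeds 1.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.DataStructs import TanimotoSimilarity
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

HIGH_CUT = 2.0  # lg(Ki) below this => high activity
LOW_CUT = 3.0  # lg(Ki) above this => low activity
MERGE_SPREAD = 1.0  # max lg(Ki) spread tolerated when merging replicates
SIMILARITY_THRESHOLD = 0.75  # MACCS Tanimoto above this => redundant pair

#: sentinel returned by :func:`merge_activity` for discordant replicates
DISCARD = "discard"


class CurationError(ValueError):
    """Invalid activity records or an impossible split request."""


@dataclass(frozen=True)
class ActivityRecord:
    """One measured inhibition constant for one ligand.

    Parameters
    ----------
    ligand_id : str
        Opaque ligand identifier.
    source_id : str
        Identifier of the measurement's origin (e.g. a complex entry code).
    ki_nM : float
        Inhibition constant in nanomolar; must be strictly positive.
    """

    ligand_id: str
    source_id: str
    ki_nM: float

    def __post_init__(self) -> None:
        if not (self.ki_nM > 0) or not math.isfinite(self.ki_nM):
            raise CurationError(
                f"record ({self.ligand_id}, {self.source_id}): "
                f"Ki must be a positive finite value in nM, got {self.ki_nM!r}"
            )

    @property
    def lg_ki(self) -> float:
        return math.log10(self.ki_nM)


@dataclass
class LigandEntry:
    """A curated ligand: structure, merged activity and class label."""

    ligand_id: str
    structure: str  # SMILES
    lg_ki: float
    activity_class: str  # "high" | "low" | "excluded"
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isfinite(self.lg_ki):
            raise CurationError(f"ligand {self.ligand_id}: lg(Ki) must be finite")


@dataclass
class CuratedDataset:
    """Curated entries plus their split assignments.

    ``split_assignment`` maps every retained ligand_id to ``"modeling"`` or
    ``"external_test"``; ``inner_split`` maps modeling ligands to ``"train"``
    or ``"internal_test"``.
    """

    entries: list[LigandEntry]
    split_assignment: dict[str, str]
    inner_split: dict[str, str]

    def subset(self, which: str) -> list[LigandEntry]:
        """Entries belonging to one of modeling/external_test/train/internal_test."""
        if which in ("modeling", "external_test"):
            return [e for e in self.entries if self.split_assignment[e.ligand_id] == which]
        if which in ("train", "internal_test"):
            return [e for e in self.entries if self.inner_split.get(e.ligand_id) == which]
        raise KeyError(which)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "ligand_id": e.ligand_id,
                    "structure": e.structure,
                    "lg_ki": e.lg_ki,
                    "activity_class": e.activity_class,
                    "split": self.split_assignment.get(e.ligand_id, ""),
                    "inner_split": self.inner_split.get(e.ligand_id, ""),
                }
            )
        return pd.DataFrame(rows)

    def save(self, csv_path: str | Path, manifest_path: str | Path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        manifest = {"split_assignment": self.split_assignment, "inner_split": self.inner_split}
        Path(manifest_path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def merge_activity(records: list[ActivityRecord]) -> float | str:
    """Merge replicate Ki records for one ligand onto the lg(Ki) scale.

    Returns the arithmetic mean of the per-record lg(Ki) values when their
    spread (max - min) is at most 1 log unit; returns :data:`DISCARD` when
    the spread exceeds 1. A single record returns its own lg(Ki).

    The result is invariant under permutation of ``records``.
    """
    if not records:
        raise CurationError("merge_activity requires at least one record")
    lgs = [r.lg_ki for r in records]
    if max(lgs) - min(lgs) > MERGE_SPREAD:
        return DISCARD
    # fsum is exactly rounded, so the mean is permutation-invariant
    return math.fsum(lgs) / len(lgs)


def assign_class(lg_ki: float) -> str:
    """Activity class for a merged lg(Ki): strict cuts at 2 and 3.

    Values in the closed interval [2, 3] belong to neither group and are
    labelled ``"excluded"``.
    """
    if not math.isfinite(lg_ki):
        raise CurationError("lg_ki must be finite")
    if lg_ki < HIGH_CUT:
        return "high"
    if lg_ki > LOW_CUT:
        return "low"
    return "excluded"


def curate_records(
    records: list[ActivityRecord], structures: dict[str, str]
) -> tuple[list[LigandEntry], dict]:
    """Merge records per ligand, assign classes, drop discordant ligands.

    Parameters
    ----------
    records : list of ActivityRecord
    structures : dict
        ligand_id -> SMILES.

    Returns
    -------
    entries, report
        ``entries`` keeps only ligands with a concordant merged lg(Ki)
        (excluded-class entries are retained in the list but flagged);
        ``report`` counts discards and lists their ids.
    """
    by_ligand: dict[str, list[ActivityRecord]] = {}
    for r in records:
        by_ligand.setdefault(r.ligand_id, []).append(r)

    entries: list[LigandEntry] = []
    discarded: list[str] = []
    missing_structure: list[str] = []
    for lid in sorted(by_ligand):
        merged = merge_activity(by_ligand[lid])
        if merged == DISCARD:
            discarded.append(lid)
            continue
        smiles = structures.get(lid)
        if smiles is None:
            missing_structure.append(lid)
            continue
        entries.append(
            LigandEntry(
                ligand_id=lid,
                structure=smiles,
                lg_ki=float(merged),
                activity_class=assign_class(float(merged)),
                sources=sorted(r.source_id for r in by_ligand[lid]),
            )
        )
    report = {
        "n_input_ligands": len(by_ligand),
        "n_discarded_discordant": len(discarded),
        "discarded_ids": discarded,
        "missing_structure_ids": missing_structure,
    }
    return entries, report


def _maccs_fp(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return MACCSkeys.GenMACCSKeys(mol)


def maccs_similarity(smiles_a: str, smiles_b: str) -> float:
    """MACCS-keys Tanimoto similarity between two SMILES."""
    fa, fb = _maccs_fp(smiles_a), _maccs_fp(smiles_b)
    if fa is None or fb is None:
        raise CurationError("unparseable SMILES in similarity computation")
    return TanimotoSimilarity(fa, fb)


def prune_redundant(
    entries: list[LigandEntry],
    threshold: float = SIMILARITY_THRESHOLD,
    within_class: bool = True,
) -> tuple[list[LigandEntry], dict]:
    """Remove structurally redundant ligands by MACCS Tanimoto similarity.

    Ligands are processed in ascending ``ligand_id`` order; a ligand is kept
    iff its similarity to every already-kept ligand (of the same activity
    class when ``within_class``) is <= ``threshold``. The strict inequality
    means a pair at exactly the threshold is retained. Re-running on the
    output removes nothing.

    Unparseable structures are excluded with a warning and listed in the
    report.
    """
    kept: list[LigandEntry] = []
    kept_fps: list = []
    removed: list[tuple[str, str, float]] = []
    unparseable: list[str] = []

    for entry in sorted(entries, key=lambda e: e.ligand_id):
        fp = _maccs_fp(entry.structure)
        if fp is None:
            warnings.warn(f"ligand {entry.ligand_id}: unparseable SMILES, excluded")
            unparseable.append(entry.ligand_id)
            continue
        conflict = None
        for other, ofp in zip(kept, kept_fps):
            if within_class and other.activity_class != entry.activity_class:
                continue
            sim = TanimotoSimilarity(fp, ofp)
            if sim > threshold:
                conflict = (other.ligand_id, sim)
                break
        if conflict is None:
            kept.append(entry)
            kept_fps.append(fp)
        else:
            removed.append((entry.ligand_id, conflict[0], conflict[1]))

    report = {
        "n_removed": len(removed),
        "removed": [
            {"ligand_id": a, "similar_to": b, "similarity": s} for a, b, s in removed
        ],
        "unparseable_ids": unparseable,
    }
    logger.info("prune_redundant: removed %d of %d entries", len(removed), len(entries))
    return kept, report


def split_dataset(
    entries: list[LigandEntry],
    modeling_fraction: float = 165 / 208,
    seed: int = 0,
    features: pd.DataFrame | None = None,
    inner_train_fraction: float = 0.7,
) -> CuratedDataset:
    """Assign ligands to modeling/external-test and train/internal-test sets.

    The external split is a seeded random draw stratified by activity class.
    The inner 7:3 split clusters the modeling ligands (k-means on
    standardized ``features`` rows, k = max(2, n // 10)) and allocates each
    cluster's members 7:3 by a seeded draw, so both halves sample the same
    structural neighbourhoods; when no features are supplied the inner split
    is a plain stratified draw.

    Only ``high``/``low`` entries participate; ``excluded`` entries are
    dropped here.
    """
    usable = [e for e in entries if e.activity_class in ("high", "low")]
    if len(usable) < 10:
        raise CurationError("need at least 10 class-labelled entries to split")
    rng = np.random.default_rng(seed)

    split_assignment: dict[str, str] = {}
    for cls in ("high", "low"):
        ids = sorted(e.ligand_id for e in usable if e.activity_class == cls)
        if len(ids) < 2:
            raise CurationError(f"class {cls!r} has fewer than 2 members")
        n_model = int(round(modeling_fraction * len(ids)))
        n_model = min(max(n_model, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        for rank, idx in enumerate(perm):
            split_assignment[ids[idx]] = "modeling" if rank < n_model else "external_test"

    modeling = [e for e in usable if split_assignment[e.ligand_id] == "modeling"]
    inner_split = _inner_split(
        modeling, features, inner_train_fraction, np.random.default_rng(seed + 1)
    )
    return CuratedDataset(entries=usable, split_assignment=split_assignment, inner_split=inner_split)


def _inner_split(
    modeling: list[LigandEntry],
    features: pd.DataFrame | None,
    train_fraction: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    ids = [e.ligand_id for e in modeling]
    if features is not None:
        feats = features.loc[[i for i in ids if i in features.index]]
        X = feats.to_numpy(dtype=float)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
        k = max(2, len(feats) // 10)
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(X)
        groups = {c: [fid for fid, lab in zip(feats.index, labels) if lab == c] for c in set(labels)}
        leftovers = [i for i in ids if i not in features.index]
        if leftovers:
            groups["_nofeat"] = leftovers
    else:
        # stratify by class instead of structure clusters
        groups = {}
        for e in modeling:
            groups.setdefault(e.activity_class, []).append(e.ligand_id)

    inner: dict[str, str] = {}
    for key in sorted(groups, key=str):
        members = sorted(groups[key])
        n_train = int(round(train_fraction * len(members)))
        perm = rng.permutation(len(members))
        for rank, idx in enumerate(perm):
            inner[members[idx]] = "train" if rank < n_train else "internal_test"
    return inner


def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    """Read activity records from CSV with columns ligand_id, source_id, ki_nM."""
    df = pd.read_csv(path, dtype={"ligand_id": str, "source_id": str})
    return [
        ActivityRecord(str(r.ligand_id), str(r.source_id), float(r.ki_nM))
        for r in df.itertuples(index=False)
    ]


def read_smiles_file(path: str | Path) -> dict[str, str]:
    """Read a .smi file (``SMILES<TAB>id`` per line) into id -> SMILES."""
    structures: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise CurationError(f"malformed SMILES line: {line!r}")
        smiles, lid = parts
        structures[lid.strip()] = smiles
    return structures
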