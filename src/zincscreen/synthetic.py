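"""Synthetic data with planted ground truth for the ZnBF-discovery pipeline.

Real curated sets of zinc-metalloenzyme ligands pair each compound with one
or more Ki measurements harvested from different complex entries, exhibit
structural redundancy (analog series), and carry an activity signal that is
concentrated in electronic descriptors. The generators here reproduce that
statistical structure with known truth labels so every downstream stage —
curation, descriptor filtering, feature selection, classification and
screening — can be exercised and scored without any external download.

Three generators share one root seed, split into named substreams
(structures / activities / descriptors / library) so each stage is
reproducible in isolation:

* :func:`generate_ligand_set` — structures from a closed fragment grammar
  (scaffold x prefix x linker x cap, where caps include the classic
  zinc-binding motifs: hydroxamic acid, sulfonamide, urea, phosphonate,
  carboxylate), lg(Ki) from a two-component distribution centred below 2
  (high activity) and above 3 (low activity), replicate Ki records with
  controllable concordant/discordant spread, and structural near-duplicates
  made by single-atom edits.
* :func:`generate_descriptor_table` — a ligands x descriptors matrix whose
  informative columns are named after the electronic descriptors the screen
  gates on, shifted between classes by a chosen standardized effect size;
  a zero-variance column and a collinear pair are always planted so the
  descriptor filter cascade has work to do.
* :func:`generate_fragment_library` — a screening library with a known
  subset of planted actives that carry ZnBF substructures and in-gate
  descriptor values.

The signal is statistical, not physical: no attempt is made to mimic real
structure-activity relationships or electron densities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.DataStructs import TanimotoSimilarity

from .curation import ActivityRecord

__all__ = [
    "SyntheticSpec",
    "SyntheticLigand",
    "LigandSet",
    "FragmentLibrary",
    "ELECTRONIC_DESCRIPTOR_NAMES",
    "generate_ligand_set",
    "generate_descriptor_table",
    "generate_fragment_library",
]

#: electronic descriptors characterizing metal binding; informative synthetic
#: columns reuse these names so the screening gate applies unchanged.
ELECTRONIC_DESCRIPTOR_NAMES = [
    "JGI8",
    "JGI9",
    "BCUTp-1h",
    "PEOE_VSA-4",
    "PEOE_VSA+1",
    "PEOE_VSA-0",
    "nAtomP",
    "HBA_Count",
]

# fragment grammar: molecule = prefix + scaffold + linker + cap, concatenated
# as SMILES. Every combination is validated with RDKit at generation time.
SCAFFOLDS = [
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "c1ccsc1",
    "C1CCCCC1",
    "C1CCNCC1",
]
PREFIXES = ["", "C", "O", "N", "F", "Cl"]
LINKERS = ["", "C", "CC", "CCC", "C(=O)", "CC(=O)N", "CN"]
ZNBF_CAPS = {
    "hydroxamate": "C(=O)NO",
    "sulfonamide": "S(=O)(=O)N",
    "urea": "NC(N)=O",
    "phosphonate": "P(=O)(O)O",
    "carboxylate": "C(=O)O",
}
DECOY_CAPS = ["C", "CC", "C(C)C", "OC", "N(C)C", "C(F)(F)F"]

DEFAULT_PLANTED_ZNBFS = list(ZNBF_CAPS)


class SyntheticSpecError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-truth generators.

    Defaults emulate the curated modelling set the pipeline targets:
    ~208 ligands at a 131:77 high:low ratio, lg(Ki) spanning [-4, 7],
    a fifth of ligands carrying replicate Ki entries, a small discordant
    fraction, ~10% near-duplicate structures, and an activity signal of
    standardized effect size 1.5 carried by the eight electronic
    descriptors among fifty columns total.
    """

    seed: int = 0
    n_ligands: int = 208
    high_fraction: float = 131 / 208
    lg_ki_range: tuple[float, float] = (-4.0, 7.0)
    dup_entry_rate: float = 0.20
    discordant_rate: float = 0.15
    near_dup_rate: float = 0.10
    n_informative_descriptors: int = 8
    n_noise_descriptors: int = 40
    effect_size: float = 1.5
    noise_sd: float = 1.0
    planted_znbf_ids: tuple[str, ...] = tuple(DEFAULT_PLANTED_ZNBFS)
    #: probability that a high-activity ligand carries a ZnBF cap
    znbf_rate_high: float = 0.85
    #: probability that a low-activity ligand carries a ZnBF cap
    znbf_rate_low: float = 0.15

    def __post_init__(self) -> None:
        if self.n_ligands < 10:
            raise SyntheticSpecError("n_ligands must be >= 10")
        if not 0 < self.high_fraction < 1:
            raise SyntheticSpecError("high_fraction must lie in (0, 1)")
        for name in ("dup_entry_rate", "discordant_rate", "near_dup_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SyntheticSpecError(f"{name} must lie in [0, 1]")
        if self.n_informative_descriptors < 0 or self.n_noise_descriptors < 0:
            raise SyntheticSpecError("descriptor counts must be non-negative")
        if self.lg_ki_range[0] >= self.lg_ki_range[1]:
            raise SyntheticSpecError("lg_ki_range must be increasing")
        if self.noise_sd <= 0:
            raise SyntheticSpecError("noise_sd must be positive")
        unknown = set(self.planted_znbf_ids) - set(ZNBF_CAPS)
        if unknown:
            raise SyntheticSpecError(f"unknown ZnBF cap ids: {sorted(unknown)}")

    def substream(self, name: str) -> np.random.Generator:
        """Named child RNG derived from the root seed."""
        streams = {"structures": 1, "activities": 2, "descriptors": 3, "library": 4}
        return np.random.default_rng([self.seed, streams[name]])


@dataclass
class SyntheticLigand:
    """One generated ligand with its ground truth."""

    ligand_id: str
    smiles: str
    true_class: str  # "high" | "low"
    lg_ki: float  # mean of the emitted records' lg(Ki)
    has_znbf: bool
    znbf_id: str | None
    near_dup_of: str | None = None
    records: list[ActivityRecord] = field(default_factory=list)


@dataclass
class LigandSet:
    """Output of :func:`generate_ligand_set`."""

    ligands: list[SyntheticLigand]

    @property
    def records(self) -> list[ActivityRecord]:
        return [r for lig in self.ligands for r in lig.records]

    @property
    def structures(self) -> dict[str, str]:
        return {lig.ligand_id: lig.smiles for lig in self.ligands}

    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ligand_id": lig.ligand_id,
                    "true_class": lig.true_class,
                    "lg_ki": lig.lg_ki,
                    "has_znbf": lig.has_znbf,
                    "znbf_id": lig.znbf_id or "",
                    "near_dup_of": lig.near_dup_of or "",
                }
                for lig in self.ligands
            ]
        ).set_index("ligand_id")

    def write(self, out_dir: str | Path) -> None:
        """Write SMILES, activity CSV and ground-truth JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lines = [f"{lig.smiles}\t{lig.ligand_id}" for lig in self.ligands]
        (out / "ligands.smi").write_text("\n".join(lines) + "\n")
        pd.DataFrame(
            [
                {"ligand_id": r.ligand_id, "source_id": r.source_id, "ki_nM": r.ki_nM}
                for r in self.records
            ]
        ).to_csv(out / "activity.csv", index=False)
        (out / "truth.json").write_text(
            json.dumps(self.truth().reset_index().to_dict(orient="records"), indent=2)
        )
        write_sdf(self.structures, out / "ligands.sdf")


def write_sdf(structures: dict[str, str], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for lid, smi in structures.items():
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            mol.SetProp("_Name", lid)
            writer.write(mol)
    finally:
        writer.close()


def _compose_smiles(rng: np.random.Generator, cap: str) -> str:
    """Draw a grammar molecule ending in ``cap``; guaranteed RDKit-valid."""
    for _ in range(20):
        smi = (
            PREFIXES[rng.integers(len(PREFIXES))]
            + SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
            + LINKERS[rng.integers(len(LINKERS))]
            + cap
        )
        if Chem.MolFromSmiles(smi) is not None:
            return smi
    # grammar components are individually valid; plain scaffold+cap fallback
    smi = SCAFFOLDS[0] + cap
    assert Chem.MolFromSmiles(smi) is not None
    return smi


def _sample_lg_ki(rng: np.random.Generator, cls: str, lo: float, hi: float) -> float:
    """Two-component activity distribution: high centred at 0.5, low at 4.5."""
    loc, scale = (0.5, 1.3) if cls == "high" else (4.5, 1.0)
    lim_lo, lim_hi = (lo, 2.0) if cls == "high" else (3.0, hi)
    for _ in range(1000):
        v = rng.normal(loc, scale)
        if lim_lo < v < lim_hi:
            return float(v)
    return float((lim_lo + lim_hi) / 2)  # pragma: no cover


def _near_dup_smiles(parent: str) -> str:
    """Single-atom edit of ``parent`` keeping MACCS Tanimoto > 0.75.

    Falls back to an exact copy (similarity 1.0) when no single-atom edit
    stays above the redundancy threshold, which only happens for very small
    parents.
    """
    from rdkit import rdBase

    ref = MACCSkeys.GenMACCSKeys(Chem.MolFromSmiles(parent))
    for variant in ("C" + parent, "N" + parent, "O" + parent, parent + "C"):
        with rdBase.BlockLogs():  # invalid candidates are rejected silently
            mol = Chem.MolFromSmiles(variant)
        if mol is None:
            continue
        if TanimotoSimilarity(ref, MACCSkeys.GenMACCSKeys(mol)) > 0.75:
            return variant
    return parent


def generate_ligand_set(spec: SyntheticSpec) -> LigandSet:
    """Generate ligand structures plus per-ligand activity records.

    Class labels are allocated deterministically (``round(n * high_fraction)``
    high ligands, shuffled over ids), so the realized class proportion always
    matches the requested one to within rounding. Duplicated ligands receive
    2-4 Ki records whose lg(Ki) spread is at most 0.8 when concordant;
    discordant ligands get one record displaced by 1.2-2.5 log units towards
    the interior of ``lg_ki_range``, forcing a spread > 1 (and hence discard
    at curation). Near-duplicates are appended as extra ligands with id
    suffix ``_nd``.
    """
    s_rng = spec.substream("structures")
    a_rng = spec.substream("activities")
    lo, hi = spec.lg_ki_range

    n = spec.n_ligands
    n_high = int(round(n * spec.high_fraction))
    classes = np.array(["high"] * n_high + ["low"] * (n - n_high))
    a_rng.shuffle(classes)

    # guarantee every planted ZnBF id occurs among high-activity ligands
    pending_znbfs = list(spec.planted_znbf_ids)

    source_counter = 0

    def next_source() -> str:
        nonlocal source_counter
        source_counter += 1
        return f"SRC{source_counter:05d}"

    ligands: list[SyntheticLigand] = []
    for i in range(n):
        lid = f"LIG{i:04d}"
        cls = str(classes[i])
        znbf_rate = spec.znbf_rate_high if cls == "high" else spec.znbf_rate_low
        znbf_id: str | None = None
        if cls == "high" and pending_znbfs:
            znbf_id = pending_znbfs.pop(0)
        elif spec.planted_znbf_ids and s_rng.random() < znbf_rate:
            znbf_id = spec.planted_znbf_ids[s_rng.integers(len(spec.planted_znbf_ids))]
        cap = ZNBF_CAPS[znbf_id] if znbf_id else DECOY_CAPS[s_rng.integers(len(DECOY_CAPS))]
        smiles = _compose_smiles(s_rng, cap)

        base = _sample_lg_ki(a_rng, cls, lo, hi)
        if a_rng.random() < spec.dup_entry_rate:
            m = int(a_rng.integers(2, 5))
            offsets = a_rng.uniform(-0.4, 0.4, m)
            offsets -= offsets.mean()
            lgs = base + offsets
            if a_rng.random() < spec.discordant_rate:
                direction = 1.0 if base <= (lo + hi) / 2 else -1.0
                # displace the record already extreme in the shift direction,
                # so the resulting lg(Ki) spread is guaranteed to exceed 1
                j = int(np.argmax(offsets)) if direction > 0 else int(np.argmin(offsets))
                lgs[j] += direction * a_rng.uniform(1.2, 2.5)
            lgs = np.clip(lgs, lo, hi)
        else:
            lgs = np.array([base])

        records = [
            ActivityRecord(lid, next_source(), float(10.0 ** lg)) for lg in lgs
        ]
        ligands.append(
            SyntheticLigand(
                ligand_id=lid,
                smiles=smiles,
                true_class=cls,
                lg_ki=float(np.mean(lgs)),
                has_znbf=znbf_id is not None,
                znbf_id=znbf_id,
                records=records,
            )
        )

    # near-duplicates: extra entries copied from the largest parents
    n_nd = int(round(spec.near_dup_rate * n))
    if n_nd:
        by_size = sorted(
            ligands,
            key=lambda lig: (-Chem.MolFromSmiles(lig.smiles).GetNumHeavyAtoms(), lig.ligand_id),
        )
        parents_pool = by_size[: max(n_nd * 2, 10)]
        idx = s_rng.choice(len(parents_pool), size=n_nd, replace=False)
        for k in sorted(idx):
            parent = parents_pool[int(k)]
            dup_id = parent.ligand_id + "_nd"
            dup_smiles = _near_dup_smiles(parent.smiles)
            dup_lg = float(np.clip(parent.lg_ki + a_rng.uniform(-0.2, 0.2), lo, hi))
            if parent.true_class == "high":
                dup_lg = min(dup_lg, 1.99)
            else:
                dup_lg = max(dup_lg, 3.01)
            ligands.append(
                SyntheticLigand(
                    ligand_id=dup_id,
                    smiles=dup_smiles,
                    true_class=parent.true_class,
                    lg_ki=dup_lg,
                    has_znbf=parent.has_znbf,
                    znbf_id=parent.znbf_id,
                    near_dup_of=parent.ligand_id,
                    records=[ActivityRecord(dup_id, next_source(), float(10.0 ** dup_lg))],
                )
            )

    return LigandSet(ligands=ligands)


def _informative_names(n: int) -> list[str]:
    names = []
    for i in range(n):
        base = ELECTRONIC_DESCRIPTOR_NAMES[i % len(ELECTRONIC_DESCRIPTOR_NAMES)]
        names.append(base if i < len(ELECTRONIC_DESCRIPTOR_NAMES) else f"{base}_{i}")
    return names


def generate_descriptor_table(
    spec: SyntheticSpec, ligands: list[SyntheticLigand] | LigandSet
) -> pd.DataFrame:
    """Ligands x descriptors table with a planted class-conditional signal.

    Informative columns (named after the electronic descriptors) are drawn
    N(effect_size, 1) for high-activity ligands and N(0, 1) for low-activity
    ones, so the standardized between-class mean difference equals
    ``spec.effect_size``. Noise columns are N(0, noise_sd) in both classes.
    A zero-variance column ``const_desc`` and a collinear pair
    ``colin_a``/``colin_b`` (|r| > 0.8, weakly informative) are always
    planted to exercise the descriptor filter cascade.
    """
    if isinstance(ligands, LigandSet):
        ligands = ligands.ligands
    if not ligands:
        raise SyntheticSpecError("ligands must be nonempty")
    rng = spec.substream("descriptors")
    n = len(ligands)
    is_high = np.array([lig.true_class == "high" for lig in ligands], dtype=float)

    cols: dict[str, np.ndarray] = {}
    for name in _informative_names(spec.n_informative_descriptors):
        cols[name] = spec.effect_size * is_high + rng.normal(0.0, 1.0, n)
    base = 0.8 * spec.effect_size * is_high + rng.normal(0.0, 1.0, n)
    cols["colin_a"] = base
    cols["colin_b"] = base + rng.normal(0.0, 0.3, n)
    cols["const_desc"] = np.full(n, 3.14)
    for i in range(spec.n_noise_descriptors):
        cols[f"noise_{i:03d}"] = rng.normal(0.0, spec.noise_sd, n)

    return pd.DataFrame(cols, index=pd.Index([lig.ligand_id for lig in ligands], name="ligand_id"))


@dataclass
class FragmentLibrary:
    """A screening library with truth labels for enrichment tests."""

    table: pd.DataFrame  # molecule_id, smiles, is_active, znbf_id
    descriptors: pd.DataFrame  # indexed by molecule_id

    @property
    def n_active(self) -> int:
        return int(self.table["is_active"].sum())

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lines = [f"{r.smiles}\t{r.molecule_id}" for r in self.table.itertuples(index=False)]
        (out / "library.smi").write_text("\n".join(lines) + "\n")
        self.descriptors.to_csv(out / "library_descriptors.csv")
        self.table.to_csv(out / "library_truth.csv", index=False)


def generate_fragment_library(
    spec: SyntheticSpec,
    n_molecules: int = 2000,
    active_fraction: float = 0.05,
    n_planted: int | None = None,
) -> FragmentLibrary:
    """Generate a small-molecule library with exactly ``k`` planted actives.

    ``k`` is ``n_planted`` when given, else ``round(n_molecules *
    active_fraction)``. Planted actives carry a ZnBF cap from
    ``spec.planted_znbf_ids`` and descriptor rows drawn from the
    high-activity class distribution (hence mostly in-gate); the remainder
    carry decoy caps and low-class descriptor rows.
    """
    rng = spec.substream("library")
    k = n_planted if n_planted is not None else int(round(n_molecules * active_fraction))
    if not 0 <= k <= n_molecules:
        raise SyntheticSpecError("planted active count out of range")

    active_flags = np.zeros(n_molecules, dtype=bool)
    if k:
        active_flags[rng.choice(n_molecules, size=k, replace=False)] = True

    rows = []
    planted_cycle = 0
    for i, flag in enumerate(active_flags):
        mid = f"FRG{i:05d}"
        if flag and spec.planted_znbf_ids:
            znbf_id = spec.planted_znbf_ids[planted_cycle % len(spec.planted_znbf_ids)]
            planted_cycle += 1
            cap = ZNBF_CAPS[znbf_id]
        else:
            znbf_id = None
            cap = DECOY_CAPS[rng.integers(len(DECOY_CAPS))]
        rows.append(
            {
                "molecule_id": mid,
                "smiles": _compose_smiles(rng, cap),
                "is_active": bool(flag),
                "znbf_id": znbf_id or "",
            }
        )
    table = pd.DataFrame(rows)

    lig_proxy = [
        SyntheticLigand(mid, "", "high" if flag else "low", 0.0, flag, None)
        for mid, flag in zip(table["molecule_id"], active_flags)
    ]
    # same class-conditional machinery as the modelling table, but drawn from
    # the library substream so the two stages stay independently reproducible
    desc = _library_descriptors(spec, lig_proxy, rng)
    return FragmentLibrary(table=table, descriptors=desc)


def _library_descriptors(
    spec: SyntheticSpec, ligands: list[SyntheticLigand], rng: np.random.Generator
) -> pd.DataFrame:
    n = len(ligands)
    is_high = np.array([lig.true_class == "high" for lig in ligands], dtype=float)
    cols: dict[str, np.ndarray] = {}
    for name in _informative_names(spec.n_informative_descriptors):
        cols[name] = spec.effect_size * is_high + rng.normal(0.0, 1.0, n)
    base = 0.8 * spec.effect_size * is_high + rng.normal(0.0, 1.0, n)
    cols["colin_a"] = base
    cols["colin_b"] = base + rng.normal(0.0, 0.3, n)
    cols["const_desc"] = np.full(n, 3.14)
    for i in range(spec.n_noise_descriptors):
        cols[f"noise_{i:03d}"] = rng.normal(0.0, spec.noise_sd, n)
    return pd.DataFrame(
        cols, index=pd.Index([lig.ligand_id for lig in ligands], name="molecule_id")
    )
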