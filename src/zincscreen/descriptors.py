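"""Molecular descriptors and the descriptor filter cascade.

Two providers fill a ligands x descriptors table:

* :func:`compute_descriptors` — an open 2D provider built on RDKit. It
  always includes the eight electronic descriptors that characterize
  metal-binding fragments (JGI8/JGI9 topological charge indices, the
  polarizability-weighted Burden eigenvalue BCUTp-1h, three
  partial-charge-binned surface-area sums PEOE_VSA-4 / PEOE_VSA+1 /
  PEOE_VSA-0, the largest-pi-system atom count nAtomP, and the
  hydrogen-bond-acceptor count HBA_Count) plus a broad panel of standard
  RDKit 2D descriptors. Quantum-chemical descriptors are not computed here;
  externally computed tables enter through :func:`read_descriptor_csv`.
* :func:`read_descriptor_csv` — ingest of precomputed tables (first column
  ligand_id).

:func:`filter_cascade` applies the three-stage descriptor filter used
before model building: drop zero-variance columns, drop columns whose
absolute correlation with lg(Ki) is below 0.15, then resolve collinear
pairs (|r| > 0.8) by deleting the member less correlated with lg(Ki).
:func:`profile_descriptors` computes the per-descriptor statistics (mu,
sigma, point-biserial correlation with the activity class, Mann-Whitney U
p-value) that drive interpretation and the screening gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors
from scipy import stats

__all__ = [
    "ELECTRONIC_DESCRIPTORS",
    "DescriptorError",
    "compute_descriptors",
    "read_descriptor_csv",
    "handle_missing",
    "filter_cascade",
    "profile_descriptors",
    "topological_charge_index",
    "bcut_polarizability_high",
    "peoe_vsa_bin",
    "n_atoms_largest_pi_system",
]


class DescriptorError(ValueError):
    """Descriptor computation or filtering failed."""


#: descriptor category per electronic descriptor (used in profiles)
ELECTRONIC_DESCRIPTORS = {
    "JGI8": "topological charge",
    "JGI9": "topological charge",
    "BCUTp-1h": "polarizability",
    "PEOE_VSA-4": "local charge",
    "PEOE_VSA+1": "local charge",
    "PEOE_VSA-0": "local charge",
    "nAtomP": "count",
    "HBA_Count": "count",
}

# MOE-style partial charge bins [lo, hi) for the three gated PEOE_VSA sums
PEOE_BINS = {
    "PEOE_VSA-4": (-0.25, -0.20),
    "PEOE_VSA+1": (0.05, 0.10),
    "PEOE_VSA-0": (-0.05, 0.00),
}

# static atomic dipole polarizabilities (A^3), CRC values for common elements
ATOMIC_POLARIZABILITY = {
    "H": 0.667, "B": 3.03, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
    "Si": 5.38, "P": 3.63, "S": 2.90, "Cl": 2.18, "Br": 3.05, "I": 5.35,
}


def topological_charge_index(mol: Chem.Mol, order: int) -> float:
    """Galvez mean topological charge index of a given order.

    The charge-term matrix is ``M = A D*`` with ``A`` the heavy-atom
    adjacency matrix and ``D*`` the inverse-square topological distance
    matrix (zero diagonal). The index sums ``|m_ij - m_ji|`` over atom pairs
    at topological distance ``order`` and divides by (n_atoms - 1).
    Molecules with fewer than two heavy atoms score 0.
    """
    n = mol.GetNumHeavyAtoms()
    if n < 2:
        return 0.0
    A = Chem.GetAdjacencyMatrix(mol).astype(float)
    D = Chem.GetDistanceMatrix(mol)
    with np.errstate(divide="ignore"):
        Dstar = np.where(D > 0, 1.0 / np.square(D), 0.0)
    M = A @ Dstar
    CT = M - M.T
    mask = np.triu(D == order, k=1)
    return float(np.abs(CT[mask]).sum() / (n - 1))


def bcut_polarizability_high(mol: Chem.Mol) -> float:
    """Highest eigenvalue of the polarizability-weighted Burden matrix.

    Diagonal entries are tabulated atomic polarizabilities; bonded pairs
    carry 0.1 x (conventional bond order, 1.5 for aromatic), terminal bonds
    get +0.01, and all other off-diagonal entries are 0.001, following the
    original Burden construction over heavy atoms.
    """
    n = mol.GetNumHeavyAtoms()
    if n == 0:
        return 0.0
    B = np.full((n, n), 0.001)
    for i, atom in enumerate(mol.GetAtoms()):
        B[i, i] = ATOMIC_POLARIZABILITY.get(atom.GetSymbol(), 1.5)
    degrees = [a.GetDegree() for a in mol.GetAtoms()]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        w = 0.1 * bond.GetBondTypeAsDouble()
        if degrees[i] == 1 or degrees[j] == 1:
            w += 0.01
        B[i, j] = B[j, i] = w
    return float(np.linalg.eigvalsh(B).max())


def _gasteiger_charges(mol: Chem.Mol) -> np.ndarray:
    AllChem.ComputeGasteigerCharges(mol)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    return np.nan_to_num(q, nan=0.0, posinf=0.0, neginf=0.0)


def peoe_vsa_bin(mol: Chem.Mol, lo: float, hi: float) -> float:
    """Sum of per-atom surface-area contributions with Gasteiger q in [lo, hi)."""
    contribs = rdMolDescriptors._CalcLabuteASAContribs(mol)[0]
    q = _gasteiger_charges(mol)
    return float(sum(v for v, qi in zip(contribs, q) if lo <= qi < hi))


def n_atoms_largest_pi_system(mol: Chem.Mol) -> int:
    """Number of atoms in the largest connected conjugated system."""
    parent = list(range(mol.GetNumAtoms()))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    touched = set()
    for bond in mol.GetBonds():
        if bond.GetIsConjugated():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            touched.update((i, j))
            parent[find(i)] = find(j)
    if not touched:
        return 0
    sizes: dict[int, int] = {}
    for i in touched:
        root = find(i)
        sizes[root] = sizes.get(root, 0) + 1
    return max(sizes.values())


# broad 2D panel: name -> callable(mol)
_RDKIT_PANEL = [
    "MolWt", "MolLogP", "MolMR", "TPSA", "LabuteASA", "HeavyAtomCount",
    "NumHDonors", "NumHAcceptors", "NumRotatableBonds", "RingCount",
    "NumAromaticRings", "NumSaturatedRings", "NumAliphaticRings",
    "FractionCSP3", "NHOHCount", "NOCount", "NumHeteroatoms",
    "BalabanJ", "BertzCT", "HallKierAlpha",
    "Chi0", "Chi1", "Chi0v", "Chi1v", "Chi2v", "Chi3v", "Chi4v",
    "Kappa1", "Kappa2", "Kappa3",
    "SMR_VSA1", "SMR_VSA5", "SMR_VSA7",
    "SlogP_VSA2", "SlogP_VSA5", "SlogP_VSA6",
    "EState_VSA2", "EState_VSA8",
    "MaxPartialCharge", "MinPartialCharge",
]


def _descriptor_row(mol: Chem.Mol) -> dict[str, float]:
    row = {
        "JGI8": topological_charge_index(mol, 8),
        "JGI9": topological_charge_index(mol, 9),
        "BCUTp-1h": bcut_polarizability_high(mol),
        "nAtomP": float(n_atoms_largest_pi_system(mol)),
        "HBA_Count": float(rdMolDescriptors.CalcNumHBA(mol)),
    }
    for name, (lo, hi) in PEOE_BINS.items():
        row[name] = peoe_vsa_bin(mol, lo, hi)
    for name in _RDKIT_PANEL:
        fn = getattr(Descriptors, name)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row[name] = float(fn(mol))
        except Exception:
            row[name] = np.nan
    return row


def compute_descriptors(structures: dict[str, str]) -> pd.DataFrame:
    """Compute the 2D descriptor panel for id -> SMILES structures.

    Unparseable SMILES are dropped with a warning; a column that is missing
    for every ligand is rejected.
    """
    rows, index = [], []
    for lid, smi in structures.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            warnings.warn(f"ligand {lid}: unparseable SMILES, dropped")
            continue
        rows.append(_descriptor_row(mol))
        index.append(lid)
    if not rows:
        raise DescriptorError("no parseable structures")
    df = pd.DataFrame(rows, index=pd.Index(index, name="ligand_id"))
    all_missing = [c for c in df.columns if df[c].isna().all()]
    if all_missing:
        raise DescriptorError(f"all-missing descriptor columns: {all_missing}")
    return df


def read_descriptor_csv(path) -> pd.DataFrame:
    """Ingest an externally computed descriptor table (first column ligand_id)."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "ligand_id"
    if df.columns.duplicated().any():
        raise DescriptorError("duplicate descriptor names in table")
    return df.astype(float)


def handle_missing(
    matrix: pd.DataFrame, max_missing_fraction: float = 0.2
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop columns with too many missing values, median-impute the rest."""
    audit: list[dict] = []
    out = matrix.copy()
    for col in list(out.columns):
        frac = float(out[col].isna().mean())
        if frac > max_missing_fraction:
            out = out.drop(columns=col)
            audit.append({"descriptor": col, "action": "dropped", "missing_fraction": frac})
        elif frac > 0:
            out[col] = out[col].fillna(out[col].median())
            audit.append({"descriptor": col, "action": "median_imputed", "missing_fraction": frac})
    return out, audit


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if (x == x[0]).all() or (y == y[0]).all():
        return 0.0
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def filter_cascade(
    matrix: pd.DataFrame,
    lg_ki: pd.Series | np.ndarray,
    activity_r_min: float = 0.15,
    pairwise_r_max: float = 0.8,
    method: str = "pearson",
) -> tuple[pd.DataFrame, list[dict]]:
    """Three-stage descriptor filter; idempotent by construction.

    1. remove zero-variance columns;
    2. remove columns with |corr to lg(Ki)| < ``activity_r_min``;
    3. for each pair with |pairwise corr| > ``pairwise_r_max`` (visited in
       descending |r|), delete the member with the lower |corr to lg(Ki)|
       (tie: the lexicographically later name).

    Returns the reduced matrix and an audit log with one entry per removal.
    """
    y = np.asarray(lg_ki, dtype=float)
    if len(y) != len(matrix):
        raise DescriptorError("activity vector does not align with matrix rows")
    if len(matrix) < 2:
        raise DescriptorError("need at least 2 ligands for correlation statistics")

    audit: list[dict] = []
    X = matrix.copy()

    # stage 1: zero variance (exact constancy; the naive var of a constant
    # column can round to a tiny nonzero value)
    for col in list(X.columns):
        v = X[col].to_numpy(dtype=float)
        if (v == v[0]).all():
            audit.append({"descriptor": col, "stage": 1, "reason": "zero variance"})
            X = X.drop(columns=col)

    # stage 2: weak correlation to activity
    target_r = {c: _corr(X[c].to_numpy(dtype=float), y, method) for c in X.columns}
    for col in list(X.columns):
        if abs(target_r[col]) < activity_r_min:
            audit.append(
                {
                    "descriptor": col,
                    "stage": 2,
                    "reason": "low activity correlation",
                    "r_lg_ki": target_r[col],
                }
            )
            X = X.drop(columns=col)

    # stage 3: collinear pairs, strongest first
    cols = list(X.columns)
    if len(cols) >= 2:
        vals = X.to_numpy(dtype=float)
        if method == "spearman":
            vals = stats.rankdata(vals, axis=0)
        C = np.corrcoef(vals, rowvar=False)
        pairs = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = C[i, j]
                if np.isfinite(r) and abs(r) > pairwise_r_max:
                    pairs.append((abs(r), cols[i], cols[j]))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        dropped: set[str] = set()
        for r_abs, a, b in pairs:
            if a in dropped or b in dropped:
                continue
            ra, rb = abs(target_r[a]), abs(target_r[b])
            if ra > rb:
                victim = b
            elif rb > ra:
                victim = a
            else:
                victim = max(a, b)  # tie: lexicographically later name
            dropped.add(victim)
            audit.append(
                {
                    "descriptor": victim,
                    "stage": 3,
                    "reason": "collinear pair",
                    "partner": a if victim == b else b,
                    "pairwise_r": r_abs,
                }
            )
        X = X.drop(columns=sorted(dropped))

    return X, audit


def profile_descriptors(
    matrix: pd.DataFrame,
    class_labels: pd.Series | np.ndarray,
    reference_class: str = "high",
    r_flag: float = 0.3,
    p_flag: float = 0.05,
) -> pd.DataFrame:
    """Per-descriptor statistics for interpretation and gate construction.

    For each column: point-biserial correlation with the activity class
    (class coded 1 for ``reference_class``), a two-sided Mann-Whitney U
    p-value between the two classes (exact enumeration when the smaller
    class has <= 8 members and there are no ties, tie-corrected normal
    approximation otherwise), and mu/sigma over the reference class (the
    population the screening gate is built from). Columns with |r| >
    ``r_flag`` and p < ``p_flag`` are flagged highly correlated.
    """
    labels = np.asarray(class_labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise DescriptorError("profile_descriptors requires exactly two classes")
    pos = labels == reference_class
    if pos.sum() == 0 or pos.sum() == len(labels):
        raise DescriptorError(f"reference class {reference_class!r} empty or exhaustive")

    rows = []
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        a, b = x[pos], x[~pos]
        r = _corr(x, pos.astype(float), "pearson")
        if (x == x[0]).all():
            p = 1.0
        else:
            exact_ok = min(len(a), len(b)) <= 8 and len(np.unique(x)) == len(x)
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
            )
            p = float(res.pvalue)
        rows.append(
            {
                "name": col,
                "mean": float(np.mean(a)),
                "sd": float(np.std(a, ddof=1)) if len(a) > 1 else 0.0,
                "r_activity": r,
                "p_value": min(p, 1.0),
                "is_electronic": col in ELECTRONIC_DESCRIPTORS,
                "category": ELECTRONIC_DESCRIPTORS.get(col, "other"),
                "highly_correlated": bool(abs(r) > r_flag and p < p_flag),
            }
        )
    return pd.DataFrame(rows).set_index("name")
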