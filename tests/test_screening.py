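"""ZnBF pattern table, descriptor gate, library screen, metal-site extraction."""

import numpy as np
import pandas as pd
import pytest

from zincscreen.classifiers import NaiveBayesClassifier
from zincscreen.descriptors import profile_descriptors
from zincscreen.screening import (
    ScreeningError,
    build_gate,
    extract_binding_atoms,
    inhibitor_search,
    load_znbf_patterns,
    rank_hits,
    screen_library,
    substructure_search,
)


@pytest.fixture(scope="module")
def patterns():
    return load_znbf_patterns()


class TestPatternTable:
    def test_shipped_table_loads_and_validates(self, patterns):
        assert len(patterns) == 15
        ids = [p.id for p in patterns]
        assert len(ids) == len(set(ids))
        for p in patterns:
            assert p.query() is not None
            assert p.denticity in ("monodentate", "bidentate")
            assert len(p.binding_atom_indices) == (2 if p.denticity == "bidentate" else 1)

    def test_invalid_smarts_rejected(self, tmp_path):
        bad = tmp_path / "p.csv"
        bad.write_text(
            "id,smarts,binding_atom_indices,denticity,provenance,note\n"
            "broken,[[[,0,monodentate,known,x\n"
        )
        with pytest.raises(ScreeningError, match="invalid SMARTS"):
            load_znbf_patterns(bad)

    def test_out_of_range_binding_atom_rejected(self, tmp_path):
        bad = tmp_path / "p.csv"
        bad.write_text(
            "id,smarts,binding_atom_indices,denticity,provenance,note\n"
            "hx,[CX3](=O)[NX3][OX2H1],9,bidentate,known,x\n"
        )
        with pytest.raises(ScreeningError, match="out of range"):
            load_znbf_patterns(bad)

    def test_carbon_binding_atom_rejected(self, tmp_path):
        bad = tmp_path / "p.csv"
        bad.write_text(
            "id,smarts,binding_atom_indices,denticity,provenance,note\n"
            "hx,[CX3](=O)[NX3][OX2H1],0,monodentate,known,x\n"
        )
        with pytest.raises(ScreeningError, match="not O/N/S/F"):
            load_znbf_patterns(bad)


class TestGate:
    @staticmethod
    def _profiles(mu, sd, name="JGI8"):
        return pd.DataFrame(
            {"mean": [mu], "sd": [sd], "is_electronic": [True]},
            index=pd.Index([name], name="name"),
        )

    def test_interval_arithmetic(self):
        gate = build_gate(self._profiles(10.0, 2.0))
        lo, hi = gate["JGI8"]
        assert lo == pytest.approx(6.08)
        assert hi == pytest.approx(13.92)

    def test_zero_sigma_degenerates_to_point(self):
        gate = build_gate(self._profiles(5.0, 0.0))
        assert gate["JGI8"] == (5.0, 5.0)

    def test_deterministic_and_missing_name_rejected(self):
        prof = self._profiles(1.0, 1.0)
        assert build_gate(prof) == build_gate(prof)
        with pytest.raises(ScreeningError):
            build_gate(prof, gated_names=["absent"])


class TestScreenLibrary:
    @staticmethod
    def _model_and_gate():
        rng = np.random.default_rng(0)
        y = np.array(["high"] * 60 + ["low"] * 60)
        X = pd.DataFrame(
            {
                "JGI8": (y == "high") * 2.0 + rng.normal(0, 1, 120),
                "noise_000": rng.normal(0, 1, 120),
            }
        )
        model = NaiveBayesClassifier().fit(X, y)
        profiles = profile_descriptors(X, y)
        gate = build_gate(profiles, gated_names=["JGI8"])
        return model, gate, profiles

    def test_center_of_gate_passes_and_tail_fails(self):
        model, gate, profiles = self._model_and_gate()
        mu = profiles.loc["JGI8", "mean"]
        sd = profiles.loc["JGI8", "sd"]
        lib = pd.DataFrame(
            {"JGI8": [mu, mu + 2.0 * sd], "noise_000": [0.0, 0.0]},
            index=["at_center", "beyond_gate"],
        )
        hits = {h.molecule_id: h for h in screen_library(lib, model, gate)}
        assert hits["at_center"].gate_results["JGI8"]["pass"]
        assert hits["at_center"].overall_pass
        assert not hits["beyond_gate"].gate_results["JGI8"]["pass"]
        assert not hits["beyond_gate"].overall_pass

    def test_missing_gated_descriptor_fails_with_reason(self):
        model, gate, _ = self._model_and_gate()
        lib = pd.DataFrame({"JGI8": [np.nan], "noise_000": [0.0]}, index=["m"])
        (hit,) = screen_library(lib, model, gate)
        assert not hit.overall_pass
        assert hit.gate_results["JGI8"]["reason"] == "descriptor missing"

    def test_tighter_multiplier_retains_subset(self):
        model, _, profiles = self._model_and_gate()
        rng = np.random.default_rng(5)
        lib = pd.DataFrame(
            {"JGI8": rng.normal(1.0, 2.0, 400), "noise_000": rng.normal(0, 1, 400)},
            index=[f"m{i}" for i in range(400)],
        )
        wide = build_gate(profiles, gated_names=["JGI8"], multiplier=1.96)
        narrow = build_gate(profiles, gated_names=["JGI8"], multiplier=1.0)
        keep_wide = {h.molecule_id for h in screen_library(lib, model, wide) if h.overall_pass}
        keep_narrow = {h.molecule_id for h in screen_library(lib, model, narrow) if h.overall_pass}
        assert keep_narrow <= keep_wide


class TestSubstructureSearch:
    def test_hydroxamate_matches_vorinostat_like_smiles(self, patterns):
        table, counts = substructure_search(
            {"vorinostat": "ONC(=O)CCCCCCC(=O)Nc1ccccc1"}, patterns
        )
        assert counts["hydroxamate"] == 1
        assert "hydroxamate" in table.iloc[0]["matched_patterns"]

    def test_methane_matches_nothing(self, patterns):
        table, counts = substructure_search({"methane": "C"}, patterns)
        assert len(table) == 0
        assert all(v == 0 for v in counts.values())

    def test_planted_fixture_counts_exactly(self, patterns):
        carriers = {
            "m1": "c1ccccc1CC(=O)NO",  # hydroxamate
            "m2": "c1ccc2ccccc2c1S(=O)(=O)N",  # sulfonamide
            "m3": "C1CCCCC1NC(N)=O",  # urea
            "m4": "c1ccccc1CCP(=O)(O)O",  # phosphonate
        }
        decoys = {f"d{i}": smi for i, smi in enumerate(
            ["CCCC", "c1ccccc1C", "C1CCCCC1OC", "CCN(C)C", "c1ccccc1CC(F)(F)F", "CCOC"]
        )}
        table, _ = substructure_search({**carriers, **decoys}, patterns)
        assert set(table["molecule_id"]) == set(carriers)

    def test_order_independent_and_union_property(self, patterns):
        lib = {
            "a": "c1ccccc1CC(=O)NO",
            "b": "c1ccsc1CCNC(N)=O",
            "c": "CCCC",
        }
        t1, _ = substructure_search(lib, patterns)
        t2, _ = substructure_search(dict(reversed(list(lib.items()))), patterns)
        assert set(t1["molecule_id"]) == set(t2["molecule_id"])
        per_pattern_union = set()
        for p in patterns:
            t, _ = substructure_search(lib, [p])
            per_pattern_union |= set(t["molecule_id"]) if len(t) else set()
        assert per_pattern_union == set(t1["molecule_id"])

    def test_inhibitor_search_requires_substructure(self, patterns):
        model_hits = TestScreenLibrary._model_and_gate()
        model, gate, profiles = model_hits
        mu = profiles.loc["JGI8", "mean"]
        lib_desc = pd.DataFrame({"JGI8": [mu, mu], "noise_000": [0.0, 0.0]}, index=["znbf", "plain"])
        structures = {"znbf": "c1ccccc1CC(=O)NO", "plain": "c1ccccc1CC"}
        hits = screen_library(lib_desc, model, gate)
        refined = inhibitor_search(hits, structures, patterns)
        outcome = {h.molecule_id: h.overall_pass for h in refined}
        assert outcome == {"znbf": True, "plain": False}
        ranked = rank_hits(refined)
        assert [h.molecule_id for h in ranked] == ["znbf"]


PDB_TEMPLATE = """\
HETATM    1 ZN    ZN A 501       0.000   0.000   0.000  1.00  0.00          ZN
HETATM    2  O1  LIG A 502       2.500   0.000   0.000  1.00  0.00           O
HETATM    3  C1  LIG A 502       2.000   0.000   0.000  1.00  0.00           C
HETATM    4  O2  LIG A 502       3.000   0.000   0.000  1.00  0.00           O
HETATM    5  N1  LIG A 502       0.000   1.900   0.000  1.00  0.00           N
HETATM    6  S1  LIG A 502       0.000   0.000   2.790  1.00  0.00           S
HETATM    7  F1  LIG A 502       1.700   1.700   1.700  1.00  0.00           F
END
"""


class TestExtractBindingAtoms:
    def test_distance_rule_selects_exactly_onsf_within_cutoff(self, tmp_path):
        pdb = tmp_path / "site.pdb"
        pdb.write_text(PDB_TEMPLATE)
        (site,) = extract_binding_atoms(pdb, metal_element="Zn", cutoff=2.8)
        names = {a["atom"].split("/")[-1]: a for a in site.candidate_atoms}
        # O1 at 2.5 in; C1 excluded by element; O2 at 3.0 out; S1 at 2.79 in;
        # F1 at sqrt(3*1.7^2)=2.944 out; N1 at 1.9 in
        assert set(names) == {"O1", "N1", "S1"}
        assert names["O1"]["distance"] == pytest.approx(2.5, abs=1e-6)
        assert names["N1"]["distance"] == pytest.approx(1.9, abs=1e-6)
        assert names["S1"]["distance"] == pytest.approx(2.79, abs=1e-6)
        assert site.denticity_by_residue == {"A/LIG502": 3}

    def test_missing_metal_rejected(self, tmp_path):
        pdb = tmp_path / "nometal.pdb"
        pdb.write_text("\n".join(PDB_TEMPLATE.splitlines()[1:]) + "\n")
        with pytest.raises(ScreeningError, match="no Zn atom"):
            extract_binding_atoms(pdb)
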