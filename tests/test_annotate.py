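"""Database parsing and the four taxonomy-aware matching rules, the
other-symbioses folding, recall summaries and novel-edge SCC ranking."""

import numpy as np
import pandas as pd
import pytest

import protnet as pn
from protnet.annotate import DBRecord, annotations_to_frame
from protnet.containers import TaxonomyTable

SYND = ["Eukaryota", "Alveolata", "Dinoflagellata", "Syndiniales",
        "Syndiniales-Group-II", "Syndiniales-Group-II-Clade-1", "fam", ""]
DINO = ["Eukaryota", "Alveolata", "Dinoflagellata", "Dinophyceae",
        "Dinophyceae", "Gymnodiniales", "Gymnodiniaceae", "Tripos"]
ACANTH = ["Eukaryota", "Rhizaria", "Radiolaria", "Radiolaria_X",
          "Acantharea", "Acantharea-Clade-F", "fam", ""]
HAPTO = ["Eukaryota", "Haptista", "Haptophyta", "Prymnesiophyta",
         "Prymnesiophyceae", "Prymnesiales", "Prymnesiaceae", "Phaeocystis"]
MAST = ["Eukaryota", "Stramenopiles", "Bigyra", "Opalozoa",
        "MAST-3", "MAST-3F", "fam", ""]
DIATOM = ["Eukaryota", "Stramenopiles", "Ochrophyta", "Bacillariophyta",
          "Bacillariophyceae", "Leptocylindrales", "fam", "Leptocylindrus"]
DINOPHYSIS = ["Eukaryota", "Alveolata", "Dinoflagellata", "Dinophyceae",
              "Dinophyceae", "Dinophysiales", "Dinophysiaceae", "Dinophysis"]
CRYPTO = ["Eukaryota", "Cryptista", "Cryptophyta", "Cryptophyceae",
          "Cryptomonadales", "Pyrenomonadales", "Geminigeraceae",
          "Teleaulax amphioxeia"]
UNRESOLVED = ["Eukaryota", "Eukaryota_X", "Eukaryota_XX", "Eukaryota_XXX",
              "unknown", "unknown", "unknown", ""]


@pytest.fixture()
def taxonomy():
    return TaxonomyTable({
        "synd": SYND, "dino": DINO, "acanth": ACANTH, "hapto": HAPTO,
        "mast": MAST, "diatom": DIATOM, "dphys": DINOPHYSIS,
        "crypto": CRYPTO, "dark": UNRESOLVED,
    })


@pytest.fixture()
def db():
    return pn.InteractionDB([
        DBRecord("r1", "Group II", "syndiniales_group", "Tripos", "genus",
                 "parasitism"),
        DBRecord("r2", "Acantharea Clade F", "radiolarian_class",
                 "Phaeocystis", "genus", "symbiosis"),
        DBRecord("r3", "MAST 3F", "mast_clade", "Leptocylindrus", "genus",
                 "symbiosis"),
        DBRecord("r4", "Dinophysis", "genus", "Teleaulax", "genus",
                 "unresolved"),
        DBRecord("r5", "Tripos", "genus", "Teleaulax", "genus", "predation"),
    ])


class TestParseDb:
    def _write(self, tmp_path, rows):
        df = pd.DataFrame(rows, columns=["record_id", "taxon_a_key",
                                         "taxon_a_rank", "taxon_b_key",
                                         "taxon_b_rank", "interaction_type"])
        path = tmp_path / "db.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_five_records(self, tmp_path):
        rows = [[f"r{i}", "A", "genus", "B", "genus", "predation"]
                for i in range(5)]
        for i, row in enumerate(rows):
            row[1] = f"A{i}"
        db = pn.parse_interaction_db(self._write(tmp_path, rows))
        assert len(db) == 5

    def test_duplicate_collapsed_with_multiplicity(self, tmp_path):
        rows = [["r1", "A", "genus", "B", "genus", "predation"],
                ["r2", "B", "genus", "A", "genus", "predation"]]
        db = pn.parse_interaction_db(self._write(tmp_path, rows))
        assert len(db) == 1
        assert db.records[0].multiplicity == 2

    def test_unknown_type_reports_line(self, tmp_path):
        rows = [["r1", "A", "genus", "B", "genus", "predation"],
                ["r2", "C", "genus", "D", "genus", "commensalism"]]
        with pytest.raises(ValueError, match="line 3.*commensalism"):
            pn.parse_interaction_db(self._write(tmp_path, rows))

    def test_unknown_rank_rejected(self, tmp_path):
        rows = [["r1", "A", "species", "B", "genus", "predation"]]
        with pytest.raises(ValueError, match="rank"):
            pn.parse_interaction_db(self._write(tmp_path, rows))


class TestMatchRules:
    def test_syndiniales_group_host_genus(self, taxonomy, db):
        (a,) = pn.match_edges([("synd", "dino")], taxonomy, db)
        assert a.status == "supported"
        assert a.match_rule == "syndiniales_group_host_genus"
        assert a.reported_types == ("parasitism",)

    def test_radiolarian_class_symbiont_genus(self, taxonomy, db):
        (a,) = pn.match_edges([("acanth", "hapto")], taxonomy, db)
        assert a.status == "supported"
        assert a.match_rule == "radiolarian_class_symbiont_genus"
        assert a.reported_types == ("other_symbioses",)

    def test_mast_clade_symbiont_genus(self, taxonomy, db):
        (a,) = pn.match_edges([("mast", "diatom")], taxonomy, db)
        assert a.status == "supported"
        assert a.match_rule == "mast_clade_symbiont_genus"
        assert a.reported_types == ("other_symbioses",)

    def test_genus_genus_and_unresolved_folding(self, taxonomy, db):
        (a,) = pn.match_edges([("dphys", "crypto")], taxonomy, db)
        assert a.status == "supported"
        assert a.match_rule == "genus_genus"
        # DB type "unresolved" is reported as other_symbioses
        assert a.reported_types == ("other_symbioses",)

    def test_species_suffix_ignored(self, taxonomy, db):
        # crypto's genus token is "Teleaulax amphioxeia"
        (a,) = pn.match_edges([("crypto", "dino")], taxonomy, db)
        assert a.status == "supported"  # Tripos-Teleaulax predation record

    def test_no_record_is_novel(self, taxonomy, db):
        (a,) = pn.match_edges([("dino", "diatom")], taxonomy, db)
        assert a.status == "novel"
        assert a.reason == "no-matching-record"

    def test_rank_unresolvable(self, taxonomy, db):
        (a,) = pn.match_edges([("dark", "dino")], taxonomy, db)
        assert a.status == "novel"
        assert a.reason == "rank-unresolvable"

    def test_symmetry_in_edge_order(self, taxonomy, db):
        for pair in [("synd", "dino"), ("acanth", "hapto"),
                     ("dphys", "crypto")]:
            (fwd,) = pn.match_edges([pair], taxonomy, db)
            (rev,) = pn.match_edges([pair[::-1]], taxonomy, db)
            assert fwd.status == rev.status
            assert fwd.match_rule == rev.match_rule
            assert fwd.reported_types == rev.reported_types

    def test_supported_plus_novel_partitions_edges(self, taxonomy, db):
        edges = [("synd", "dino"), ("dino", "diatom"), ("mast", "diatom"),
                 ("dark", "hapto")]
        anns = pn.match_edges(edges, taxonomy, db)
        statuses = [a.status for a in anns]
        assert statuses.count("supported") + statuses.count("novel") == 4
        assert all(t != "unresolved"
                   for a in anns for t in a.reported_types)

    def test_missing_taxonomy_raises(self, taxonomy, db):
        with pytest.raises(KeyError, match="ghost"):
            pn.match_edges([("ghost", "dino")], taxonomy, db)


class TestRecallSummary:
    def test_hand_enumerated_counts(self, taxonomy):
        db = pn.InteractionDB([
            DBRecord("r1", "Group II", "syndiniales_group", "Tripos",
                     "genus", "parasitism"),
            DBRecord("r2", "Tripos", "genus", "Leptocylindrus", "genus",
                     "parasitism"),
            DBRecord("r3", "Absentia", "genus", "Missingia", "genus",
                     "parasitism"),
            DBRecord("r4", "Tripos", "genus", "Nullia", "genus",
                     "parasitism"),
        ])
        anns = pn.match_edges([("synd", "dino")], taxonomy, db)
        summary = pn.summarize_recall(anns, db, taxonomy,
                                      ["synd", "dino", "diatom"])
        row = summary.loc["parasitism"]
        assert row["db_records"] == 4
        assert row["db_records_both_present"] == 2  # r1 and r2
        assert row["supported_edges_found"] == 1

    def test_empty_db_all_zero(self, taxonomy):
        db = pn.InteractionDB([])
        summary = pn.summarize_recall([], db, taxonomy, ["dino"])
        assert (summary.to_numpy() == 0).all()

    def test_full_coverage_synthetic_truth_all_supported(self):
        """Every planted edge covered by the database must be annotated
        supported - no false novels among covered planted edges."""
        cfg = pn.SyntheticConfig(n_asvs=24, n_months=48, n_planted_edges=10,
                                 db_coverage=1.0, n_decoy_records=5, seed=3)
        _, tax, truth = pn.generate_community(cfg)
        db = pn.generate_interaction_db(truth, tax, cfg)
        anns = pn.match_edges(list(truth.planted_edges), tax, db)
        assert all(a.status == "supported" for a in anns)


class TestNovelEdgeScc:
    def _clr(self, cols):
        return pd.DataFrame(cols, index=[f"s{i}"
                                         for i in range(len(next(iter(
                                             cols.values()))))])

    def _novel(self, edge):
        return pn.EdgeAnnotation(edge=edge, status="novel")

    def test_monotone_pair_scc_one(self):
        clr = self._clr({"a": [1.0, 2, 3, 5], "b": [2.0, 4, 9, 11]})
        table = pn.novel_edge_scc([self._novel(("a", "b"))], clr)
        assert table["scc"][0] == pytest.approx(1.0)

    def test_hand_rank_fixture(self):
        clr = self._clr({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 1, 4, 3, 5]})
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4: rho = 1 - 6*4/(5*24) = 0.8
        table = pn.novel_edge_scc([self._novel(("x", "y"))], clr)
        assert table["scc"][0] == pytest.approx(0.8)

    def test_threshold_inclusive(self):
        anns = [self._novel(("a", "b"))]
        table = pd.DataFrame({"scc": [0.9, 0.64, 0.5]})
        strong = table["scc"].abs() >= 0.64
        assert strong.sum() == 2  # "at least" semantics
        # and through the API: an SCC exactly at threshold is flagged
        n = 40
        rng = np.random.default_rng(1)
        x = rng.standard_normal(n)
        clr = self._clr({"a": x, "b": x})
        out = pn.novel_edge_scc([self._novel(("a", "b"))],
                                clr, report_threshold=1.0)
        assert bool(out["strong"][0])

    def test_constant_series_excluded(self):
        clr = self._clr({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5],
                         "c": [2.0, 1, 4, 3]})
        anns = [self._novel(("a", "b")), self._novel(("a", "c"))]
        with pytest.warns(UserWarning, match="SCC undefined"):
            table = pn.novel_edge_scc(anns, clr)
        assert len(table) == 1
        assert table["asv_b"][0] == "c"

    def test_sorted_by_absolute_scc(self, rng):
        x = np.arange(20.0)
        clr = self._clr({
            "a": x, "b": -x, "c": x + 3 * rng.standard_normal(20),
            "d": rng.standard_normal(20),
        })
        anns = [self._novel(("a", "b")), self._novel(("a", "c")),
                self._novel(("a", "d"))]
        table = pn.novel_edge_scc(anns, clr)
        assert (table["abs_scc"].diff().dropna() <= 0).all()
        assert table.iloc[0]["scc"] == pytest.approx(-1.0)

    def test_frame_export_roundtrip(self, taxonomy, db):
        anns = pn.match_edges([("synd", "dino"), ("dino", "diatom")],
                              taxonomy, db)
        frame = annotations_to_frame(anns)
        assert list(frame["status"]) == ["supported", "novel"]
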