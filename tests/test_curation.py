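"""Curation pipeline: filtering, aggregation, labelling, enrichment."""

import numpy as np
import pytest

from molscreen import synthetic
from molscreen.curation import (
    BioactivityRecord,
    CurationConfig,
    TargetDataset,
    aggregate_duplicates,
    curate,
    enrich_negatives,
    filter_records,
    label_by_threshold,
    pairwise_sequence_identity,
    select_modelled_targets,
)


def _rec(cid="c", target="T1", value=100.0, **kw):
    defaults = dict(
        compound_id=cid, smiles="CCO", target_id=target,
        standard_value_nm=value, pchembl=kw.pop("pchembl", 5.0),
    )
    defaults.update(kw)
    return BioactivityRecord(**defaults)


class TestFilterRecords:
    def test_toy_table_keeps_only_conforming(self, toy_records, default_config):
        kept = filter_records(toy_records, default_config)
        assert [r.compound_id for r in kept] == ["ok1", "ok2", "ok3"]

    def test_empty_input(self, default_config):
        assert filter_records([], default_config) == []

    def test_matches_per_predicate_oracle(self, default_config):
        """Survivors equal the intersection of independent per-predicate filters."""
        rng = np.random.default_rng(42)
        records = []
        for i in range(50):
            records.append(
                _rec(
                    cid=f"c{i}",
                    target_type=str(rng.choice(["single_protein", "other"])),
                    taxon=str(rng.choice(["Homo sapiens", "Danio rerio"])),
                    assay_type=str(rng.choice(["binding", "functional"])),
                    standard_type=str(rng.choice(["IC50", "Ki", "other"])),
                    pchembl=float(rng.uniform(4, 9)) if rng.random() < 0.7 else None,
                )
            )
        cfg = default_config
        oracle = set(range(50))
        oracle &= {i for i, r in enumerate(records) if r.target_type in cfg.allowed_target_types}
        oracle &= {i for i, r in enumerate(records) if r.taxon in cfg.allowed_taxa}
        oracle &= {i for i, r in enumerate(records) if r.assay_type in cfg.allowed_assay_types}
        oracle &= {i for i, r in enumerate(records) if r.standard_type in cfg.allowed_standard_types}
        oracle &= {i for i, r in enumerate(records) if r.pchembl is not None}
        kept = filter_records(records, cfg)
        assert {r.compound_id for r in kept} == {f"c{i}" for i in sorted(oracle)}
        # order preserved
        assert [r.compound_id for r in kept] == [f"c{i}" for i in sorted(oracle)]

    def test_malformed_record_reports_index(self, default_config):
        records = [_rec(cid="good"), _rec(cid="bad", standard_relation="~~")]
        with pytest.raises(ValueError, match="index 1"):
            filter_records(records, default_config)


class TestAggregateDuplicates:
    def test_odd_count_median(self):
        recs = [_rec(cid="x", value=v) for v in (100.0, 200.0, 400.0)]
        out = aggregate_duplicates(recs)
        assert len(out) == 1 and out[0].standard_value_nm == 200.0

    def test_single_record_unchanged(self):
        rec = _rec(cid="solo", value=123.0)
        assert aggregate_duplicates([rec]) == [rec]

    def test_even_count_median_is_central_mean(self):
        recs = [_rec(cid="x", value=v) for v in (100.0, 200.0)]
        assert aggregate_duplicates(recs)[0].standard_value_nm == 150.0

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        recs = [
            _rec(cid=f"c{rng.integers(5)}", target=f"T{rng.integers(2)}", value=float(v))
            for v in rng.integers(1, 50000, size=30)
        ]
        once = aggregate_duplicates(recs)
        assert aggregate_duplicates(once) == once

    def test_provenance_from_closest_record(self):
        recs = [
            _rec(cid="x", value=100.0, doc_year=2001),
            _rec(cid="x", value=190.0, doc_year=2002),
            _rec(cid="x", value=400.0, doc_year=2003),
        ]
        out = aggregate_duplicates(recs)[0]
        assert out.standard_value_nm == 190.0 and out.doc_year == 2002


class TestLabelByThreshold:
    @pytest.mark.parametrize(
        "value,expected",
        [(5000.0, "active"), (10000.0, "active"), (15000.0, None),
         (20000.0, "inactive"), (50000.0, "inactive")],
    )
    def test_threshold_zones(self, value, expected, default_config):
        out = label_by_threshold([_rec(cid="c", value=value)], default_config)
        ds = out["T1"]
        got = "active" if "c" in ds.actives else "inactive" if "c" in ds.inactives else None
        assert got == expected

    def test_counts_match_elementwise_oracle(self, default_config):
        rng = np.random.default_rng(7)
        values = rng.integers(1, 60000, size=20).astype(float)
        recs = [_rec(cid=f"c{i}", value=v) for i, v in enumerate(values)]
        out = label_by_threshold(recs, default_config)["T1"]
        assert len(out.actives) == int(np.sum(values <= 10000))
        assert len(out.inactives) == int(np.sum(values >= 20000))

    def test_contradictory_relations_dropped(self, default_config):
        recs = [
            _rec(cid="gt_low", value=5000.0, standard_relation=">"),   # could exceed 10 uM
            _rec(cid="lt_high", value=50000.0, standard_relation="<"),  # could be below 20 uM
            _rec(cid="le_low", value=5000.0, standard_relation="<="),
            _rec(cid="ge_high", value=50000.0, standard_relation=">="),
        ]
        out = label_by_threshold(recs, default_config)["T1"]
        assert set(out.actives) == {"le_low"} and set(out.inactives) == {"ge_high"}


class TestSelectModelledTargets:
    @pytest.mark.parametrize("n_actives,included", [(99, False), (100, True)])
    def test_min_actives_boundary(self, n_actives, included):
        cfg = CurationConfig()
        ds = {"T1": TargetDataset("T1", {f"a{i}": "CCO" for i in range(n_actives)}, {})}
        assert (["T1"] if included else []) == select_modelled_targets(ds, cfg)

    def test_count_comparison(self):
        cfg = CurationConfig(min_actives=100)
        ds = {
            t: TargetDataset(t, {f"a{i}": "CCO" for i in range(n)}, {})
            for t, n in (("T1", 50), ("T2", 100), ("T3", 250))
        }
        assert select_modelled_targets(ds, cfg) == ["T2", "T3"]


def _identity_oracle(seq_a, seq_b):
    """Full Needleman-Wunsch (affine via large alphabet of states not needed:
    linear DP with the same open/extend penalties, Gotoh algorithm)."""
    match, mismatch, gopen, gext = 1.0, -1.0, -4.0, -2.0
    n, m = len(seq_a), len(seq_b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq_b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq_a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gopen + gext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gopen + gext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gopen, X[i - 1][j] + gext, Y[i - 1][j] + gopen)
            Y[i][j] = max(M[i][j - 1] + gopen, Y[i][j - 1] + gext, X[i][j - 1] + gopen)
    # traceback to count identities and columns
    best = max(M[n][m], X[n][m], Y[n][m])
    # recover one optimal path
    i, j = n, m
    state = max(((M[n][m], "M"), (X[n][m], "X"), (Y[n][m], "Y")))[1]
    ident = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == "M":
            s = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            if seq_a[i - 1] == seq_b[j - 1]:
                ident += 1
            prev = max(
                ((M[i - 1][j - 1], "M"), (X[i - 1][j - 1], "X"), (Y[i - 1][j - 1], "Y"))
            )[1]
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            cands = [(M[i - 1][j] + gopen, "M"), (X[i - 1][j] + gext, "X"), (Y[i - 1][j] + gopen, "Y")]
            prev = max(cands)[1]
            i, state = i - 1, prev
        else:
            cands = [(M[i][j - 1] + gopen, "M"), (Y[i][j - 1] + gext, "Y"), (X[i][j - 1] + gopen, "X")]
            prev = max(cands)[1]
            j, state = j - 1, prev
    return best, 100.0 * ident / cols


class TestSequenceIdentity:
    def test_self_identity(self):
        assert pairwise_sequence_identity("MKV", "MKV") == 100.0

    def test_disjoint_sequences(self):
        assert pairwise_sequence_identity("AAAA", "WWWW") == 0.0

    def test_symmetric(self):
        a, b = "MKVLAWQR", "MKVAWQ"
        assert pairwise_sequence_identity(a, b) == pairwise_sequence_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_sequence_identity("", "MKV")

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(19)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            a = "".join(rng.choice(aas, size=50))
            b = "".join(rng.choice(aas, size=50))
            oracle_score, oracle_ident = _identity_oracle(a, b)
            got = pairwise_sequence_identity(a, b)
            # optimal alignments may tie; identities agree within one column's worth
            assert got == pytest.approx(oracle_ident, abs=100.0 / 50)


def _dataset(tid, n_act, n_inact, prefix=""):
    return TargetDataset(
        tid,
        {f"{prefix}a{i}": "CCO" for i in range(n_act)},
        {f"{prefix}i{i}": "CCN" for i in range(n_inact)},
    )


class TestEnrichNegatives:
    def test_descending_identity_order_with_floor(self):
        datasets = {
            "A": _dataset("A", 3, 1, "A"),
            "B": _dataset("B", 0, 1, "B"),
            "C": _dataset("C", 0, 5, "C"),
            "D": _dataset("D", 0, 9, "D"),
        }
        seqs = synthetic.generate_target_sequences(
            {"A": 100.0, "B": 80.0, "C": 30.0, "D": 10.0}, seed=5
        )
        cfg = CurationConfig(min_actives=1)
        out = enrich_negatives(datasets, seqs, cfg)
        donors = [d for _, d, _ in out["A"].enrichment_provenance]
        assert donors == ["B", "C"]  # B first (80%), then C (30%); D below the 20% floor
        assert len(out["A"].inactives) == 3 and not out["A"].shortfall

    def test_balanced_target_untouched(self):
        datasets = {"A": _dataset("A", 2, 2)}
        out = enrich_negatives(datasets, {}, CurationConfig(min_actives=1))
        assert out["A"].inactives == datasets["A"].inactives
        assert out["A"].enrichment_provenance == []

    def test_shortfall_flag_when_donors_exhausted(self):
        datasets = {
            "A": _dataset("A", 10, 1, "A"),
            "B": _dataset("B", 0, 2, "B"),
        }
        seqs = synthetic.generate_target_sequences({"A": 100.0, "B": 60.0}, seed=6)
        out = enrich_negatives(datasets, seqs, CurationConfig(min_actives=1))
        # brute force: the only eligible spares are B's two inactives
        assert len(out["A"].inactives) == 3
        assert out["A"].shortfall

    def test_excess_inactives_downsampled_with_seed(self):
        datasets = {"A": _dataset("A", 3, 10)}
        cfg = CurationConfig(min_actives=1)
        out1 = enrich_negatives(datasets, {}, cfg, seed=9)
        out2 = enrich_negatives(datasets, {}, cfg, seed=9)
        assert len(out1["A"].inactives) == 3
        assert out1["A"].inactives == out2["A"].inactives

    def test_missing_sequence_errors_with_target_name(self):
        datasets = {"A": _dataset("A", 2, 0), "B": _dataset("B", 0, 5, "B")}
        with pytest.raises(KeyError, match="A"):
            enrich_negatives(datasets, {"B": "MKV" * 30}, CurationConfig(min_actives=1))


class TestCuratePipeline:
    def test_report_matches_generator_manifest(self, default_config):
        spec = synthetic.TableSpec(seed=4)
        records, manifest = synthetic.generate_bioactivity_table(spec, default_config)
        _, report = curate(records, default_config)
        for key in ("n_input", "after_target_type", "after_taxon", "after_assay_type",
                    "after_standard_type", "after_pchembl", "after_aggregation",
                    "n_active", "n_inactive", "n_gray_zone", "modelled_targets"):
            assert report[key] == manifest[key], key

    def test_set_level_order_independence(self, default_config):
        spec = synthetic.TableSpec(seed=8)
        records, _ = synthetic.generate_bioactivity_table(spec, default_config)
        ds1, _ = curate(records, default_config)
        ds2, _ = curate(list(reversed(records)), default_config)
        for tid in ds1:
            assert set(ds1[tid].actives) == set(ds2[tid].actives)
            assert set(ds1[tid].inactives) == set(ds2[tid].inactives)

    def test_unparseable_smiles_dropped_and_counted(self, default_config):
        records = [_rec(cid="good"), _rec(cid="broken", smiles="xx$$nope")]
        datasets, report = curate(records, default_config)
        assert report["n_unparseable_smiles"] == 1

    def test_salt_stripping_keeps_largest_fragment(self):
        cfg = CurationConfig(min_actives=1, strip_salts=True)
        records = [_rec(cid="salted", smiles="CC(=O)Oc1ccccc1C(=O)O.[Na+]", value=100.0)]
        datasets, _ = curate(records, cfg)
        assert datasets["T1"].actives["salted"] == "CC(=O)Oc1ccccc1C(=O)O"

    def test_actives_inactives_disjoint(self, default_config):
        spec = synthetic.TableSpec(seed=12)
        records, _ = synthetic.generate_bioactivity_table(spec, default_config)
        datasets, _ = curate(records, default_config)
        for ds in datasets.values():
            assert not (ds.actives.keys() & ds.inactives.keys())
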