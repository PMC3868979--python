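import numpy as np
import pytest

from trnaswitch.detect import (
    SwitchCall,
    analyze_mask,
    attribute_positions,
    call_switches,
    control_comparison,
    summarize_species,
)
from trnaswitch.io_formats import filter_pseudogenes
from trnaswitch.mask_align import MaskSpec, mask_triplet
from trnaswitch.phylo import DistanceMatrix
from trnaswitch.records import SpeciesRepertoire
from trnaswitch.simulate import SimConfig, simulate_repertoire

from conftest import make_record, make_sequence


def _masked_with_keys(rng, keys):
    """One masked record per (gene_id, group_key) pair, same species."""
    out = []
    for gid, key in keys:
        seq = make_sequence(rng, 72)
        seq = seq[:33] + key + seq[36:]
        rec = make_record(seq, anticodon_start=33, gene_id=gid)
        out.append(mask_triplet(rec, MaskSpec()))
    return out


def _table(ids, entries):
    n = len(ids)
    vals = np.zeros((n, n))
    idx = {g: i for i, g in enumerate(ids)}
    for (a, b), d in entries.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = d
    return DistanceMatrix(tuple(ids), vals)


class TestCallSwitches:
    def test_nearer_different_anticodon_is_switched(self, rng):
        # X (CCT): nearest CCT at 0.4, nearest TCT at 0.1 -> switched
        masked = _masked_with_keys(
            rng, [("X", "CCT"), ("C2", "CCT"), ("T1", "TCT"), ("T2", "TCT")]
        )
        pt = _table(
            ["X", "C2", "T1", "T2"],
            {("X", "C2"): 0.4, ("X", "T1"): 0.1, ("X", "T2"): 0.5,
             ("C2", "T1"): 0.5, ("C2", "T2"): 0.5, ("T1", "T2"): 0.05},
        )
        calls = {c.gene_id: c for c in call_switches(pt, masked)}
        x = calls["X"]
        assert x.switched and x.evaluated
        assert x.d_same == pytest.approx(0.4)
        assert x.d_diff == pytest.approx(0.1)
        assert x.nearest_same_id == "C2"
        assert x.nearest_diff_id == "T1"
        assert x.changed_positions == {1}

    def test_singleton_anticodon_not_evaluated(self, rng):
        masked = _masked_with_keys(
            rng, [("X", "GAT"), ("T1", "TCT"), ("T2", "TCT")]
        )
        pt = _table(
            ["X", "T1", "T2"],
            {("X", "T1"): 0.01, ("X", "T2"): 0.5, ("T1", "T2"): 0.3},
        )
        calls = {c.gene_id: c for c in call_switches(pt, masked)}
        assert not calls["X"].evaluated
        assert not calls["X"].switched
        assert calls["X"].d_same is None

    def test_exact_tie_is_not_switched(self, rng):
        masked = _masked_with_keys(
            rng, [("X", "CCT"), ("C2", "CCT"), ("T1", "TCT")]
        )
        pt = _table(
            ["X", "C2", "T1"],
            {("X", "C2"): 0.2, ("X", "T1"): 0.2, ("C2", "T1"): 0.3},
        )
        calls = {c.gene_id: c for c in call_switches(pt, masked)}
        assert calls["X"].evaluated and not calls["X"].switched

    def test_epsilon_below_tie_is_switched(self, rng):
        masked = _masked_with_keys(
            rng, [("X", "CCT"), ("C2", "CCT"), ("T1", "TCT")]
        )
        pt = _table(
            ["X", "C2", "T1"],
            {("X", "C2"): 0.2, ("X", "T1"): 0.2 - 1e-4, ("C2", "T1"): 0.3},
        )
        calls = {c.gene_id: c for c in call_switches(pt, masked)}
        assert calls["X"].switched

    def test_zero_zero_tie_not_switched(self, rng):
        masked = _masked_with_keys(
            rng, [("X", "CCT"), ("C2", "CCT"), ("T1", "TCT")]
        )
        pt = _table(
            ["X", "C2", "T1"], {("X", "C2"): 0.0, ("X", "T1"): 0.0, ("C2", "T1"): 0.0}
        )
        calls = {c.gene_id: c for c in call_switches(pt, masked)}
        assert not calls["X"].switched

    def test_nearest_tie_breaks_lexicographically(self, rng):
        masked = _masked_with_keys(
            rng, [("X", "CCT"), ("b", "TCT"), ("a", "TCT"), ("C2", "CCT")]
        )
        pt = _table(
            ["X", "b", "a", "C2"],
            {("X", "b"): 0.1, ("X", "a"): 0.1, ("X", "C2"): 0.4,
             ("b", "a"): 0.01, ("b", "C2"): 0.5, ("a", "C2"): 0.5},
        )
        calls = {c.gene_id: c for c in call_switches(pt, masked)}
        assert calls["X"].nearest_diff_id == "a"

    def test_id_mismatch_rejected(self, rng):
        masked = _masked_with_keys(rng, [("X", "CCT"), ("Y", "TCT")])
        pt = _table(["X", "Z"], {("X", "Z"): 0.1})
        with pytest.raises(ValueError, match="match"):
            call_switches(pt, masked)

    def test_invariant_under_record_permutation(self):
        rep, _ = simulate_repertoire(SimConfig(seed=13))
        kept = filter_pseudogenes(rep.records)
        analysis = analyze_mask(kept, MaskSpec())
        flipped = call_switches(
            analysis.patristic, list(reversed(analysis.masked))
        )
        by_id = {c.gene_id: c for c in flipped}
        for c in analysis.calls:
            assert by_id[c.gene_id] == c

    def test_locality_of_removal(self, rng):
        # removing a record that is nobody's nearest neighbor leaves all
        # other calls unchanged (distances held fixed)
        masked = _masked_with_keys(
            rng,
            [("A1", "CCT"), ("A2", "CCT"), ("B1", "TCT"), ("B2", "TCT"),
             ("FAR", "GAT")],
        )
        ids = ["A1", "A2", "B1", "B2", "FAR"]
        entries = {
            ("A1", "A2"): 0.02, ("B1", "B2"): 0.02, ("A1", "B1"): 0.3,
            ("A1", "B2"): 0.35, ("A2", "B1"): 0.32, ("A2", "B2"): 0.33,
            ("A1", "FAR"): 2.0, ("A2", "FAR"): 2.0, ("B1", "FAR"): 2.0,
            ("B2", "FAR"): 2.0,
        }
        full = {
            c.gene_id: c
            for c in call_switches(_table(ids, entries), masked)
        }
        assert all(
            "FAR" not in (c.nearest_same_id, c.nearest_diff_id)
            for g, c in full.items() if g != "FAR"
        )
        sub_ids = ids[:4]
        sub_entries = {k: v for k, v in entries.items() if "FAR" not in k}
        sub = {
            c.gene_id: c
            for c in call_switches(_table(sub_ids, sub_entries), masked[:4])
        }
        for g in sub_ids:
            assert sub[g].d_same == full[g].d_same
            assert sub[g].d_diff == full[g].d_diff
            assert sub[g].switched == full[g].switched


class TestAttributePositions:
    def _call(self, key, partner_key, rng):
        masked = _masked_with_keys(
            rng, [("X", key), ("S", key), ("P", partner_key)]
        )
        pt = _table(
            ["X", "S", "P"], {("X", "S"): 0.4, ("X", "P"): 0.1, ("S", "P"): 0.5}
        )
        return {c.gene_id: c for c in call_switches(pt, masked)}["X"]

    def test_first_position_transition(self, rng):
        assert self._call("TCT", "CCT", rng).changed_positions == {1}

    def test_all_positions(self, rng):
        assert self._call("AAA", "CCC", rng).changed_positions == {1, 2, 3}

    def test_non_switched_call_is_contract_error(self, rng):
        masked = _masked_with_keys(rng, [("X", "CCT"), ("Y", "CCT")])
        call = SwitchCall(
            gene_id="X", species_id="Sp", amino_acid="Arg", group_key="CCT",
            switched=False,
        )
        with pytest.raises(ValueError, match="switched"):
            attribute_positions(call, masked)


class TestSummarize:
    def _mk(self, switched_positions, n_eval=10, species="Sp"):
        calls = []
        for i in range(n_eval):
            pos = (
                frozenset(switched_positions[i])
                if i < len(switched_positions)
                else frozenset()
            )
            calls.append(
                SwitchCall(
                    gene_id=f"g{i}", species_id=species, amino_acid="Arg",
                    group_key="CCT", evaluated=True, switched=bool(pos),
                    changed_positions=pos,
                )
            )
        return calls

    def test_no_switches_zero_proportion(self):
        s = summarize_species(self._mk([]))
        assert s.n_evaluated == 10
        assert s.proportion_switched == 0.0

    def test_position_counting_convention(self):
        # {1},{1},{1,3}: each call counts once per differing position
        s = summarize_species(self._mk([{1}, {1}, {1, 3}]))
        assert s.n_switched == 3
        assert s.position_counts == {1: 3, 2: 0, 3: 1}
        assert sum(s.position_counts.values()) >= s.n_switched

    def test_zero_evaluated_proportion_undefined(self):
        calls = [
            SwitchCall(
                gene_id="g", species_id="Sp", amino_acid="Arg",
                group_key="CCT", evaluated=False,
            )
        ]
        assert summarize_species(calls).proportion_switched is None

    def test_mixed_species_rejected(self):
        calls = self._mk([], n_eval=1) + self._mk([], n_eval=1, species="Other")
        with pytest.raises(ValueError, match="species"):
            summarize_species(calls)


class TestControlComparison:
    def test_identical_families_no_switches_all_zero(self):
        rep, _ = simulate_repertoire(
            SimConfig(seed=4, delta_within=0.0, n_switches=0,
                      pseudogene_rate=0.0)
        )
        summaries = control_comparison(rep)
        for label, s in summaries.items():
            assert s.n_switched == 0, label
            assert s.proportion_switched in (0.0, None)

    def test_anticodon_mask_exceeds_controls_with_injected_switches(self):
        rep, truth = simulate_repertoire(SimConfig(seed=7))
        kept = SpeciesRepertoire(
            rep.species_id, filter_pseudogenes(rep.records), rep.domain_of_life
        )
        summaries = control_comparison(kept)
        anti = summaries["anticodon"].proportion_switched
        ctrl = [
            s.proportion_switched or 0.0
            for label, s in summaries.items()
            if label != "anticodon"
        ]
        assert len(ctrl) == 6
        assert anti > np.mean(ctrl)

    def test_fast_evolving_control_window_flags_more_than_anticodon(self):
        # elevated substitution rate inside the first control window makes
        # the control triplet polymorphic: control discrepancies must exceed
        # the (zero-switch) anticodon proportion
        rep, _ = simulate_repertoire(
            SimConfig(seed=11, n_switches=0,
                      rate_multiplier_windows={(2, 5): 40.0})
        )
        kept = SpeciesRepertoire(
            rep.species_id, filter_pseudogenes(rep.records), rep.domain_of_life
        )
        summaries = control_comparison(kept)
        anti = summaries["anticodon"].proportion_switched or 0.0
        assert (summaries["ctrl_A"].proportion_switched or 0.0) > anti
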