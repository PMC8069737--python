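"""The synthetic-family generator: templates, deletion operator, truth
replay and label recovery."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apxsig import (
    ABSENT,
    SimulationConfig,
    apply_proximal_deletions,
    classify,
    classify_batch,
    make_template,
    profile_sequence,
    replay_edits,
    simulate_dataset,
    write_fasta,
)


class TestMakeTemplate:
    def test_apx_template_is_the_reference(self, scheme):
        assert make_template("APX", scheme) == scheme.reference_sequence

    @pytest.mark.parametrize(
        "label,expected_label,expected_subtype",
        [
            ("APX", "APX", "none"),
            ("APX-R", "APX-R", "none"),
            ("APX-L", "APX-L", "none"),
            ("proto-APX-R", "hybrid", "proto-APX-R"),
            ("proto-APX-L", "hybrid", "proto-APX-L"),
        ],
    )
    def test_templates_classify_as_their_family(
        self, scheme, label, expected_label, expected_subtype
    ):
        call = classify(profile_sequence(make_template(label, scheme), scheme), scheme)
        assert (call.label, call.subtype) == (expected_label, expected_subtype)

    def test_apx_l_template_lost_both_proximal_positions(self, scheme):
        profile = profile_sequence(make_template("APX-L", scheme), scheme)
        assert profile.residue_at[163] == ABSENT
        assert profile.residue_at[172] == ABSENT

    def test_unknown_label_rejected(self, scheme):
        with pytest.raises(ValueError, match="unknown label"):
            make_template("APX-Z", scheme)


class TestProximalDeletions:
    def test_removes_163_and_172_keeping_n_terminal_sites(self, scheme):
        rng = np.random.default_rng(4)
        edited, ops = apply_proximal_deletions(scheme.reference_sequence, scheme, rng)
        assert len(ops) == 2 and all(op[0] == "del" for op in ops)
        assert all(3 <= len(op[2]) <= 8 for op in ops)
        profile = profile_sequence(edited, scheme)
        assert profile.residue_at[163] == ABSENT
        assert profile.residue_at[172] == ABSENT
        for pos in (30, 32, 38, 41, 42):
            assert profile.residue_at[pos] == scheme.residue_at(pos)

    def test_fixed_seed_reproduces_windows(self, scheme):
        out1 = apply_proximal_deletions(
            scheme.reference_sequence, scheme, np.random.default_rng(8)
        )
        out2 = apply_proximal_deletions(
            scheme.reference_sequence, scheme, np.random.default_rng(8)
        )
        assert out1 == out2

    def test_short_sequence_rejected(self, scheme):
        with pytest.raises(ValueError, match="too short|does not cover"):
            apply_proximal_deletions("M" * 50, scheme, np.random.default_rng(0))


class TestSimulateDataset:
    def test_zero_rates_recover_all_labels_exactly(self, scheme):
        config = SimulationConfig(
            composition={lab: 5 for lab in
                         ("APX", "APX-R", "APX-L", "proto-APX-R", "proto-APX-L")},
            background_substitution_rate=0.0,
            indel_rate=0.0,
            seed=1,
        )
        records, truths = simulate_dataset(config, scheme)
        calls = classify_batch(records, scheme)
        assert all(
            (c.label, c.subtype) == (t.true_label, t.true_subtype)
            for c, t in zip(calls, truths)
        )

    def test_truth_replay_reproduces_every_sequence(self, scheme):
        records, truths = simulate_dataset(SimulationConfig(seed=23), scheme)
        for rec, truth in zip(records, truths):
            assert replay_edits(scheme.reference_sequence, truth.edit_script) \
                == rec.sequence

    def test_same_seed_gives_byte_identical_fasta(self, scheme, tmp_path):
        paths = []
        for run in (1, 2):
            records, _ = simulate_dataset(SimulationConfig(seed=99), scheme)
            path = tmp_path / f"run{run}.fa"
            write_fasta(records, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(background_substitution_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(composition={"APX": -1})
        with pytest.raises(ValueError):
            SimulationConfig(composition={"not-a-family": 3})

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_truth_replay_property_across_seeds(self, seed):
        from apxsig import ReferenceScheme

        scheme = ReferenceScheme()
        config = SimulationConfig(
            composition={"APX": 1, "APX-L": 1, "proto-APX-L": 1}, seed=seed
        )
        records, truths = simulate_dataset(config, scheme)
        for rec, truth in zip(records, truths):
            assert replay_edits(scheme.reference_sequence, truth.edit_script) \
                == rec.sequence


class TestSignatureDegradation:
    def test_hybrid_fraction_matches_binomial_closed_form(self, scheme):
        """With unprotected signature positions mutating at rate r, the
        fraction of planted APX miscalled as hybrid follows
        1 - (1 - r*19/20)^5 (each of the five positions changes
        independently with probability r*19/20; any single change off
        the APX tuple yields a hybrid)."""
        r, n = 0.2, 150
        config = SimulationConfig(
            composition={"APX": n},
            background_substitution_rate=r,
            indel_rate=0.0,
            protect_signature_windows=False,
            seed=31,
        )
        records, _ = simulate_dataset(config, scheme)
        calls = classify_batch(records, scheme)
        observed = sum(c.label == "hybrid" for c in calls) / n
        p = 1 - (1 - r * 19 / 20) ** 5
        ci = 1.96 * math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= ci, (observed, p, ci)
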