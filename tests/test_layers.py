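"""Anti-noise layer switch, key-slice selection, and error-probability math."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from toothbox.geometry import ClassLabel, LayerLabel
from toothbox.layers import (
    LAYER_CLASS,
    LAYER_SEQUENCE,
    AntiNoiseLayerLabeler,
    LayerLabeling,
    SwitchConfig,
    anti_noise_switch,
    consecutive_error_probability,
    select_key_slices,
)

N, C, O = ClassLabel.NO_TOOTH, ClassLabel.CROWN, ClassLabel.OVERLAP


def clean_sequence(lengths):
    """Noise-free class labels for 5 region lengths (bottom to top)."""
    out = []
    for layer, n in zip(LAYER_SEQUENCE, lengths):
        out += [LAYER_CLASS[layer]] * n
    return out


class TestConsecutiveErrorProbability:
    def test_published_two_and_three_error_values(self):
        assert consecutive_error_probability(0.05, 2) == pytest.approx(0.0025)
        assert consecutive_error_probability(0.05, 3) == pytest.approx(0.000125)

    def test_zero_error_rate(self):
        assert consecutive_error_probability(0.0, 5) == 0.0

    @given(st.floats(0.01, 0.99), st.integers(1, 9))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_decreasing_in_run_length(self, p, k):
        assert consecutive_error_probability(p, k + 1) < consecutive_error_probability(p, k)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            consecutive_error_probability(1.5, 2)
        with pytest.raises(ValueError):
            consecutive_error_probability(0.1, 0)


class TestAntiNoiseSwitch:
    def test_clean_five_region_trace(self):
        labels = [N, N, N, C, C, C, O, O, O, C, C, C, N, N, N]
        lab = anti_noise_switch(labels, SwitchConfig(confirm_run=3))
        expected = [l for l in LAYER_SEQUENCE for _ in range(3)]
        assert lab.layer_labels == expected
        assert lab.boundaries == [3, 6, 9, 12]

    def test_lone_spike_does_not_switch(self):
        labels = [N, N, C, N, N, N, C, C, C]
        lab = anti_noise_switch(labels, SwitchConfig(confirm_run=3))
        assert lab.layer_labels == [LayerLabel.LOWER_NO_TOOTH] * 6 + [
            LayerLabel.LOWER_CROWN
        ] * 3
        assert lab.boundaries == [6, 9, 9, 9]

    def test_constant_input_never_switches(self):
        lab = anti_noise_switch([N] * 8, SwitchConfig())
        assert lab.layer_labels == [LayerLabel.LOWER_NO_TOOTH] * 8
        assert lab.boundaries == [8, 8, 8, 8]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            anti_noise_switch([], SwitchConfig())

    def test_confirm_run_one_switches_immediately(self):
        lab = anti_noise_switch([N, C, N, N], SwitchConfig(confirm_run=1))
        # the lone crown slice switches; the following no-tooth labels are
        # not the next expected class (overlap), so the state holds
        assert lab.layer_labels == [
            LayerLabel.LOWER_NO_TOOTH,
            LayerLabel.LOWER_CROWN,
            LayerLabel.LOWER_CROWN,
            LayerLabel.LOWER_CROWN,
        ]

    def test_top_to_bottom_scan_is_mirror_of_bottom_to_top(self):
        labels = clean_sequence((2, 3, 2, 3, 2))
        up = anti_noise_switch(labels, SwitchConfig(3, "bottom_to_top"))
        down = anti_noise_switch(labels[::-1], SwitchConfig(3, "top_to_bottom"))
        assert down.layer_labels == up.layer_labels[::-1]

    @given(
        st.lists(st.sampled_from([N, C, O]), min_size=1, max_size=60),
        st.integers(1, 4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_layer_state_never_decreases(self, labels, confirm_run):
        lab = anti_noise_switch(labels, SwitchConfig(confirm_run=confirm_run))
        order = {l: i for i, l in enumerate(LAYER_SEQUENCE)}
        states = [order[l] for l in lab.layer_labels]
        assert all(a <= b for a, b in zip(states, states[1:]))

    def test_noise_bursts_shorter_than_confirm_run_never_change_labels(self):
        rng = np.random.default_rng(11)
        lengths = (6, 9, 6, 9, 6)
        confirm = 3
        clean = clean_sequence(lengths)
        reference = anti_noise_switch(clean, SwitchConfig(confirm)).layer_labels
        boundaries = np.cumsum((0,) + lengths)[:-1]
        # positions at distance >= confirm_run from every region boundary
        safe = [
            i for i in range(len(clean))
            if all(abs(i - b) >= confirm for b in boundaries[1:])
        ]
        for _ in range(300):
            corrupted = list(clean)
            start = int(rng.choice(safe))
            burst = int(rng.integers(1, confirm))  # length < confirm_run
            options = [c for c in (N, C, O) if c != clean[start]]
            wrong = options[int(rng.integers(len(options)))]
            for j in range(start, min(start + burst, len(clean))):
                if j in safe:
                    corrupted[j] = wrong
            lab = anti_noise_switch(corrupted, SwitchConfig(confirm))
            assert lab.layer_labels == reference

    def test_json_round_trip(self):
        lab = anti_noise_switch([N, N, N, C, C, C], SwitchConfig())
        back = LayerLabeling.from_json_obj(lab.to_json_obj())
        assert back.layer_labels == lab.layer_labels
        assert back.boundaries == lab.boundaries


class TestSelectKeySlices:
    def test_tenth_and_last_tenth_of_each_crown_region(self):
        # lower crown occupies slices 20..59 (length 40)
        labels = clean_sequence((20, 40, 6, 20, 10))
        lab = anti_noise_switch(labels, SwitchConfig())
        keys = select_key_slices(lab)
        assert {29, 50} <= set(keys)  # 1-based 10th = offset 9; 40-10 = 50
        assert keys == sorted(set(keys))
        assert len(keys) <= 4

    def test_short_region_clamps_and_deduplicates(self):
        labels = clean_sequence((3, 5, 4, 25, 3))
        lab = anti_noise_switch(labels, SwitchConfig())
        with pytest.warns(UserWarning, match="clamped"):
            keys = select_key_slices(lab)
        lower = [k for k in keys if lab.layer_labels[k] == LayerLabel.LOWER_CROWN]
        assert lower == [3, 7]  # offsets 0 and min(9, 4) in a 5-slice region

    def test_length_19_region_collapses_to_one_key(self):
        labels = clean_sequence((3, 19, 4, 25, 3))
        lab = anti_noise_switch(labels, SwitchConfig())
        with pytest.warns(UserWarning):
            keys = select_key_slices(lab)
        lower = [k for k in keys if lab.layer_labels[k] == LayerLabel.LOWER_CROWN]
        assert lower == [3 + 9]  # min(9, 18) == max(19 - 10, 0) == 9

    def test_empty_crown_region_is_an_error(self):
        labels = clean_sequence((4, 5, 4, 0, 0))
        lab = anti_noise_switch(labels, SwitchConfig())
        with pytest.raises(ValueError, match="upper_crown"):
            select_key_slices(lab)


class TestEstimatorWrapper:
    def test_transform_matches_function(self):
        labels = [N, N, N, C, C, C, O, O, O]
        est = AntiNoiseLayerLabeler(confirm_run=3)
        assert est.transform(labels).layer_labels == anti_noise_switch(
            labels, SwitchConfig(3)
        ).layer_labels

    def test_sklearn_clone_and_params(self):
        est = AntiNoiseLayerLabeler(confirm_run=2)
        cloned = clone(est)
        assert cloned.get_params()["confirm_run"] == 2
        cloned.set_params(confirm_run=4)
        assert cloned.confirm_run == 4
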