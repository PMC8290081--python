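"""Shared fixtures: one full synthetic offline run, reused across modules."""

from dataclasses import replace

import numpy as np
import pytest

from cueloop import decoder, features, io, preprocess, synth


@pytest.fixture(scope="session")
def default_spec():
    return synth.SimulationSpec(seed=11)


@pytest.fixture(scope="session")
def noblink_spec(default_spec):
    return replace(default_spec, blink=synth.BlinkSpec(amplitude_uv=0.0))


@pytest.fixture(scope="session")
def small_recording(default_spec):
    """Reduced-scale recording (10 trials/block) for I/O and preprocessing tests."""
    sch = synth.make_schedule(
        default_spec, seed=11, trials_per_block=10, animals_per_block=1
    )
    return synth.generate_recording(default_spec, sch, seed=11)


@pytest.fixture(scope="session")
def offline_epochs(default_spec):
    """Full-protocol recording through the complete offline cleaning chain."""
    sch = synth.make_schedule(default_spec, seed=11)
    rec = synth.generate_recording(default_spec, sch, seed=11)
    rec = preprocess.highpass(rec, mode="offline")
    rec = preprocess.remove_blinks_rls(rec)
    rec = io.extract_channels(rec, "model60")
    return preprocess.reject_epochs(io.epoch(rec))


@pytest.fixture(scope="session")
def cue_epochs(offline_epochs):
    kept = offline_epochs.kept_only()
    return kept.select(np.isin(kept.labels, ["smoking", "neutral"]))


@pytest.fixture(scope="session")
def amplitude_decoder(cue_epochs):
    """Decoder trained on amplitude-domain clusters of the session recording."""
    clusters = features.select_features(
        cue_epochs, domains=("amplitude",), n_perm=300, seed=11
    )
    X = features.assemble_features(cue_epochs, clusters)
    return decoder.train(X, cue_epochs.labels, seed=0, clusters=clusters)


@pytest.fixture()
def constant_decoder(amplitude_decoder):
    """A decoder that always outputs score 0.5."""
    d = amplitude_decoder
    return decoder.TrainedDecoder(
        weights=np.zeros_like(d.weights),
        bias=0.0,
        feat_mean=np.zeros_like(d.feat_mean),
        feat_sd=np.ones_like(d.feat_sd),
        sigmoid_a=1.0,
        sigmoid_b=0.0,
        clusters=d.clusters,
    )
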