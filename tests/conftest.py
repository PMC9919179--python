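import numpy as np
import pytest

from icumotion.agreement import percent_agreement
from icumotion.classifier import ClassifierConfig, LabelStream, classify_recording
from icumotion.io import process_session
from icumotion.simulate import NoiseModel, default_protocols, simulate_recording


@pytest.fixture
def config():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


class ProcessedRun:
    """A simulated protocol run taken through the full pipeline once."""

    def __init__(self, kind: str, seed: int = 7, configuration: str = "MCL-TR",
                 noise: NoiseModel | None = None):
        script = default_protocols()[kind]
        self.script = script
        self.recording = simulate_recording(
            script, noise or NoiseModel(seed=seed), configuration=configuration)
        self.frame = process_session(
            self.recording.chest, self.recording.thigh, script.calibration_window)
        self.predicted = classify_recording(self.frame)
        n = min(len(self.predicted), len(self.recording.truth))
        self.truth = LabelStream(self.recording.truth.labels[:n], source="rater")
        self.report = percent_agreement(
            self.truth, LabelStream(self.predicted.labels[:n]))


@pytest.fixture(scope="session")
def natural_run():
    return ProcessedRun("natural")


@pytest.fixture(scope="session")
def strict_run():
    return ProcessedRun("strict")


@pytest.fixture(scope="session")
def healthcare_run():
    return ProcessedRun("healthcare_provider")


@pytest.fixture(scope="session")
def cycling_run():
    return ProcessedRun("bed_cycling")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
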