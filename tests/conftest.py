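import pytest

from stemlinc.pipeline import PipelineConfig, run_pipeline
from stemlinc.synthetic_data import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default noiseless synthetic bundle with planted ground truth."""
    d = tmp_path_factory.mktemp("bundle")
    truth = generate_bundle(SynthConfig(seed=42), d)
    return d, truth


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """Full pipeline run over the default bundle."""
    d, truth = bundle
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig.from_yaml(d / "config.yaml", out)
    report = run_pipeline(cfg)
    return d, truth, out, report


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Bundle with multiplicative expression noise, for robustness sweeps."""
    d = tmp_path_factory.mktemp("noisy")
    truth = generate_bundle(SynthConfig(seed=7, noise_sd=0.05), d)
    return d, truth


SMALL = dict(
    n_coding=60, n_linc=40, n_modules=3, module_lincs=2, module_coding=5,
    n_hes_specific=6, n_contaminants=3, n_patchy=3, n_purifying=4,
)


@pytest.fixture()
def small_bundle(tmp_path):
    d = tmp_path / "small"
    truth = generate_bundle(SynthConfig(seed=5, **SMALL), d)
    return d, truth
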