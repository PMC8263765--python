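import pytest

from methylnode.pipeline import RunConfig, run_pipeline
from methylnode.synthetic import (
    GeneratorConfig,
    generate_calibration_plate,
    generate_cohort,
    implied_operating_characteristics,
)


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """A small complete study on disk: plate + cohort CSVs at study scale."""
    outdir = tmp_path_factory.mktemp("demo_study")
    cfg = GeneratorConfig(seed=7)
    generate_calibration_plate(cfg).to_csv(outdir / "plate.csv", index=False)
    cohort = generate_cohort(cfg)
    paths = cohort.write(outdir)
    paths["plate"] = outdir / "plate.csv"
    paths["outdir"] = outdir
    paths["config"] = cfg
    paths["cohort"] = cohort
    return paths


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Full-pipeline run on a 500-per-arm cohort plus the generator's truth.

    The truth operating characteristics come from a percent-level Monte
    Carlo driven by the config alone, independent of the Ct-level pipeline
    being checked.
    """
    outdir = tmp_path_factory.mktemp("recovery")
    cfg = GeneratorConfig(seed=11, n_malignant=500, n_benign=500)
    cohort = generate_cohort(cfg)
    cohort.write(outdir)
    config = RunConfig(
        ct_table=str(outdir / "ct_table.csv"),
        metadata=str(outdir / "metadata.csv"),
        outdir=str(outdir / "run"),
        mode="prospective",
        seed=0,
    )
    report = run_pipeline(config)
    truth = implied_operating_characteristics(cfg, threshold=8.5, n=100_000, seed=0)
    return {"report": report, "truth": truth, "config": cfg}
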