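import pytest

from sepsisrules import CohortSpec, PlantedRule, PredictorSpec, generate_cohort, parse_rule


@pytest.fixture(scope="session")
def simple_predictors():
    """Three unbounded Gaussian predictors; fast to sample, easy to reason
    about analytically."""
    return (
        PredictorSpec("GCS", mean=10.0, sd=3.0, worst_mode="minimum"),
        PredictorSpec("Bilirubin", mean=2.5, sd=2.0, worst_mode="maximum"),
        PredictorSpec("Potassium", mean=4.2, sd=0.8,
                      worst_mode="extreme_from_reference", reference_interval=(3.7, 5.1)),
    )


@pytest.fixture(scope="session")
def planted_rule():
    return parse_rule("GCS <= 8 & Bilirubin > 2", "planted")


@pytest.fixture(scope="session")
def planted_cohort(simple_predictors, planted_rule):
    """n=800 cohort whose death risk is driven by one planted 2-condition
    rule (log-odds weight 2.0 over a -2.0 baseline)."""
    spec = CohortSpec(
        n=800,
        predictors=simple_predictors,
        planted_rules=(PlantedRule(planted_rule, 2.0),),
        intercept=-2.0,
        seed=20260901,
    )
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort(simple_predictors):
    """Outcome independent of the predictors (no planted rules)."""
    spec = CohortSpec(n=600, predictors=simple_predictors, intercept=-0.69, seed=77)
    return spec, generate_cohort(spec)
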