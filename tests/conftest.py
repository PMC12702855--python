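import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort (47 dev / 18 test patients, 20 controls),
    generated once per test session."""
    from strokekin.synthetic import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig())


@pytest.fixture(scope="session")
def lasso_protocol_runs(default_cohort):
    """Ten replicate runs of the full prediction protocol on the default
    cohort: label noise and CV folds re-seeded per replicate, nested-CV
    internal metrics, final refit, independent-test metrics and linear-SHAP
    explanation of every final model."""
    from strokekin._rng import substream
    from strokekin.explanation import linear_shap
    from strokekin.prediction import (
        cross_validate,
        default_model_specs,
        evaluate,
        fit_final,
    )
    from strokekin.synthetic import GeneratorConfig, assign_fma

    feats = default_cohort.features
    pat = feats[feats["group"] == "patient"]
    specs = default_model_specs(["lasso", "linear"])
    runs = []
    for seed in range(10):
        f = feats.copy()
        f.loc[pat.index, "fma_ul"] = assign_fma(
            pat.copy(), GeneratorConfig(), rng=substream(seed, "fma")
        )
        dev = f[f["cohort"] == "development"]
        test = f[f["cohort"] == "test"]
        res = cross_validate(dev, specs, seed=seed)
        final = fit_final(dev, specs["lasso"], res["lasso"].chosen_params, seed=seed)
        test_metrics = evaluate(final, test, dev["subject_id"].to_list())
        expl = linear_shap(final, dev, f[f["group"] == "patient"])
        runs.append(
            {
                "seed": seed,
                "lasso_internal_r2": res["lasso"].internal_r2,
                "linear_internal_r2": res["linear"].internal_r2,
                "test_r2": test_metrics["r2"],
                "test_mae": test_metrics["mae"],
                "final_model": final,
                "explanation": expl,
            }
        )
    return runs
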