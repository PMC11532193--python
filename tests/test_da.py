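"""Differential-abundance pipeline: filtering, offsets, null behaviour, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from scipy import stats

from robustcounts import AbundanceStudy, fit_all_taxa, gen_multitaxon, prevalence_filter, run_da
from robustcounts.cli import main


def make_study(n_samples=60, n_taxa=40, signal_fraction=0.0, effect=0.0, seed=0, **kw):
    counts, x, truth = gen_multitaxon(
        n_samples=n_samples, n_taxa=n_taxa, signal_fraction=signal_fraction,
        effect=effect, seed=seed, **kw,
    )
    metadata = pd.DataFrame({"exposure": x})
    return AbundanceStudy(counts=counts, metadata=metadata), truth


def test_prevalence_filter_edges():
    counts = pd.DataFrame(
        [[0] * 19 + [1], [1] * 20], index=["rare", "common"],
        columns=[f"s{i}" for i in range(20)],
    )
    kept, report = prevalence_filter(counts, 0.10)
    assert list(kept.index) == ["common"]
    assert report["dropped"] == ["rare"]
    kept0, _ = prevalence_filter(counts, 0.0)
    assert kept0.shape[0] == 2
    with pytest.raises(ValueError):
        prevalence_filter(counts, 1.5)


def test_prevalence_filter_matches_counting_oracle():
    rng = np.random.default_rng(4)
    n_taxa, n_samples = 100, 40
    presence = rng.uniform(size=(n_taxa, 1)) > rng.uniform(size=(n_taxa, n_samples))
    counts = pd.DataFrame(
        presence.astype(int) * rng.integers(1, 50, size=(n_taxa, n_samples)),
        index=[f"t{j}" for j in range(n_taxa)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    kept, _ = prevalence_filter(counts, 0.25)
    brute = [
        f"t{j}" for j in range(n_taxa)
        if np.count_nonzero(counts.values[j]) / n_samples >= 0.25
    ]
    assert list(kept.index) == brute


def test_tss_offset_invariance_under_count_doubling():
    """Doubling every count doubles library sizes, so the TSS offset absorbs
    the change: identical exposure estimates and p-values."""
    study, _ = make_study(seed=5)
    res1 = fit_all_taxa(study, "exposure", method="sandwich_hc3")
    doubled = AbundanceStudy(counts=2 * study.counts, metadata=study.metadata)
    res2 = fit_all_taxa(doubled, "exposure", method="sandwich_hc3")
    ok = res1["converged"] & res2["converged"]
    np.testing.assert_allclose(
        res1.loc[ok, "estimate"], res2.loc[ok, "estimate"], atol=1e-7
    )
    np.testing.assert_allclose(res1.loc[ok, "p"], res2.loc[ok, "p"], atol=1e-7)


def test_global_null_yields_no_bh_discoveries():
    study, _ = make_study(n_samples=100, n_taxa=60, signal_fraction=0.0, seed=8)
    res, report = run_da(study, "exposure", method="sandwich_hc3", prevalence=0.05)
    assert (res["p_bh"].dropna() < 0.05).sum() == 0


def test_results_invariant_to_taxon_and_sample_order():
    study, _ = make_study(seed=13)
    res = fit_all_taxa(study, "exposure", method="poisson_naive")
    rng = np.random.default_rng(1)
    tperm = rng.permutation(study.counts.index)
    sperm = rng.permutation(study.counts.columns)
    shuffled = AbundanceStudy(
        counts=study.counts.loc[tperm, sperm],
        metadata=study.metadata.loc[sperm],
    )
    res_shuf = fit_all_taxa(shuffled, "exposure", method="poisson_naive")
    np.testing.assert_allclose(
        res.loc[tperm, "estimate"], res_shuf["estimate"], atol=1e-9
    )
    np.testing.assert_allclose(res.loc[tperm, "p_bh"], res_shuf["p_bh"], atol=1e-9)


def test_sandwich_agrees_with_naive_on_equidispersed_counts():
    """With Poisson (equidispersed) counts the robust and model-based
    p-values nearly coincide: rank correlation > 0.99."""
    study, _ = make_study(n_samples=400, n_taxa=50, seed=21, size=np.inf)
    naive = fit_all_taxa(study, "exposure", method="poisson_naive")
    robust = fit_all_taxa(study, "exposure", method="sandwich_hc3")
    ok = naive["converged"] & robust["converged"]
    rho = stats.spearmanr(naive.loc[ok, "p"], robust.loc[ok, "p"]).statistic
    assert rho > 0.99


def test_sandwich_controls_false_positives_better_than_naive():
    """Mirrors the qualitative benchmark ordering: with overdispersed NB
    counts and a detectable effect on 30% of taxa, naive Poisson SEs call a
    large share of null taxa while the sandwich calls far fewer.  (False
    positives are counted directly; at strong effects total-sum scaling
    itself shifts null relative abundances, which inflates every method's
    FDR denominator and would blur the comparison.)"""
    study, truth = make_study(
        n_samples=200, n_taxa=100, signal_fraction=0.3, effect=1.0, seed=30,
    )
    res_s = fit_all_taxa(study, "exposure", method="sandwich_hc3")
    res_n = fit_all_taxa(study, "exposure", method="poisson_naive")

    def false_pos(res):
        called = (res["p_bh"] < 0.05).fillna(False).values
        return int(np.sum(called & ~truth))

    assert false_pos(res_s) <= false_pos(res_n)
    assert false_pos(res_n) > 0.2 * (~truth).sum()  # naive visibly overcalls


def test_null_taxa_indistinguishable_when_effect_is_zero():
    """Signal labels with effect=0 are statistically inert: KS test cannot
    separate their p-values from the nulls'."""
    study, truth = make_study(
        n_samples=150, n_taxa=100, signal_fraction=0.3, effect=0.0, seed=17,
    )
    res = fit_all_taxa(study, "exposure", method="sandwich_hc3")
    p = res["p"].values
    ok = res["converged"].values
    ks = stats.ks_2samp(p[ok & truth], p[ok & ~truth])
    assert ks.pvalue > 0.01


def test_constant_exposure_rejected():
    study, _ = make_study(seed=2)
    study.metadata["flat"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        fit_all_taxa(study, "flat")


def test_categorical_exposure_and_adjuster_coding():
    study, _ = make_study(n_samples=80, seed=3)
    study.metadata["group"] = np.where(study.metadata["exposure"] > 0.5, "case", "ctrl")
    study.metadata["batch"] = np.tile(["a", "b"], 40)
    res = fit_all_taxa(study, "group", adjust_covariates=["batch"], method="poisson_naive")
    assert res["converged"].any()
    with pytest.raises(ValueError, match="2 levels"):
        study.metadata["tri"] = np.tile(["a", "b", "c", "a"], 20)
        fit_all_taxa(study, "tri")


def test_mismatched_sample_ids_rejected():
    counts = pd.DataFrame([[1, 2]], index=["t0"], columns=["s0", "s1"])
    metadata = pd.DataFrame({"x": [0.1, 0.9]}, index=["s0", "sX"])
    with pytest.raises(ValueError, match="sample identifiers"):
        AbundanceStudy(counts=counts, metadata=metadata)


def test_dafit_cli_roundtrip(tmp_path):
    counts, x, _ = gen_multitaxon(n_samples=40, n_taxa=15, seed=6)
    counts_path = tmp_path / "counts.tsv"
    meta_path = tmp_path / "meta.tsv"
    out_path = tmp_path / "results.tsv"
    counts.to_csv(counts_path, sep="\t")
    pd.DataFrame({"exposure": x}).to_csv(meta_path, sep="\t")
    runner = CliRunner()
    result = runner.invoke(
        main,
        [
            "dafit", "--counts", str(counts_path), "--metadata", str(meta_path),
            "--exposure", "exposure", "--method", "sandwich_hc3",
            "--prevalence", "0.05", "--out", str(out_path),
        ],
    )
    assert result.exit_code == 0, result.output
    res = pd.read_csv(out_path, sep="\t", comment="#", index_col=0)
    assert {"estimate", "se", "p", "p_bh"} <= set(res.columns)


def test_dafit_cli_config_file_with_flag_override(tmp_path):
    counts, x, _ = gen_multitaxon(n_samples=40, n_taxa=10, seed=7)
    counts_path = tmp_path / "counts.tsv"
    meta_path = tmp_path / "meta.tsv"
    counts.to_csv(counts_path, sep="\t")
    pd.DataFrame({"exposure": x}).to_csv(meta_path, sep="\t")
    config = tmp_path / "cfg.yaml"
    config.write_text(
        f"counts: {counts_path}\nmetadata: {meta_path}\n"
        f"exposure: exposure\nmethod: poisson_naive\nout: {tmp_path/'a.tsv'}\n"
    )
    runner = CliRunner()
    # config alone
    r1 = runner.invoke(main, ["dafit", "--config", str(config)])
    assert r1.exit_code == 0, r1.output
    res = pd.read_csv(tmp_path / "a.tsv", sep="\t", comment="#", index_col=0)
    assert (res["method"] == "poisson_naive").all()
    # flag beats config
    r2 = runner.invoke(
        main,
        ["dafit", "--config", str(config), "--method", "sandwich_hc3",
         "--out", str(tmp_path / "b.tsv")],
    )
    assert r2.exit_code == 0, r2.output
    res2 = pd.read_csv(tmp_path / "b.tsv", sep="\t", comment="#", index_col=0)
    assert (res2["method"] == "sandwich_hc3").all()


def test_benchmark_cli_smoke(tmp_path):
    runner = CliRunner()
    result = runner.invoke(
        main,
        ["benchmark", "--families", "poisson", "--settings", "2,0",
         "--methods", "poisson_naive", "--reps", "20", "--seed", "1",
         "--out", str(tmp_path)],
    )
    assert result.exit_code == 0, result.output
    assert (tmp_path / "setting1_poisson.tsv").exists()
    assert (tmp_path / "run_report.json").exists()
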