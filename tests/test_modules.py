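"""Module registry I/O and the four scoring routes, each checked against an
independent oracle on small printed inputs."""

import numpy as np
import pandas as pd
import pytest

from prognomod.containers import ExpressionMatrix
from prognomod.modules import (
    ModuleDefinition,
    ModuleRegistry,
    RegistryFormatError,
    compute_all_scores,
    match_genes,
    read_module_registry,
    score_centroid_correlation,
    score_first_pc,
    score_median,
    score_published_model,
    write_module_registry,
)


def _expr(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


# ---------------------------------------------------------------------------
# Registry I/O


def test_gmt_without_sidecar_defaults_to_median(tmp_path):
    gmt = tmp_path / "m.gmt"
    gmt.write_text("modA\tdesc\tTP53\tBRCA1\nmodB\tdesc\tESR1\tERBB2\tMKI67\n")
    reg = read_module_registry(gmt)
    assert len(reg) == 2
    assert reg.counts_by_mode() == {"median": 2}
    assert reg["modB"].genes == ["ESR1", "ERBB2", "MKI67"]


def test_sidecar_assigns_modes_and_counts(tmp_path):
    gmt = tmp_path / "m.gmt"
    gmt.write_text("modA\tdesc\tTP53\tBRCA1\nmodB\tdesc\tESR1\tERBB2\tMKI67\n")
    sidecar = tmp_path / "m.json"
    sidecar.write_text('{"modB": {"mode": "first_pc"}}')
    reg = read_module_registry(gmt, sidecar)
    assert reg.counts_by_mode() == {"median": 1, "first_pc": 1}


def test_duplicate_module_name_reports_line_number(tmp_path):
    gmt = tmp_path / "m.gmt"
    gmt.write_text("modA\tdesc\tTP53\tBRCA1\nmodA\tdesc\tESR1\tMKI67\tAR\n")
    with pytest.raises(RegistryFormatError, match=":2"):
        read_module_registry(gmt)


def test_sidecar_referencing_unknown_module_is_an_error(tmp_path):
    gmt = tmp_path / "m.gmt"
    gmt.write_text("modA\tdesc\tTP53\tBRCA1\n")
    sidecar = tmp_path / "m.json"
    sidecar.write_text('{"ghost": {"mode": "median"}}')
    with pytest.raises(RegistryFormatError, match="ghost"):
        read_module_registry(gmt, sidecar)


def test_full_collection_mode_counts_total_323(tmp_path):
    """The four construction routes: 221 median + 77 first-PC + 22 centroid
    correlation + 3 published-model modules."""
    modules = []
    for i in range(221):
        modules.append(ModuleDefinition(f"med_{i}", [f"A{i}", f"B{i}"], mode="median"))
    for i in range(77):
        modules.append(ModuleDefinition(f"pc_{i}", [f"C{i}", f"D{i}", f"E{i}"], mode="first_pc"))
    for i in range(22):
        modules.append(
            ModuleDefinition(
                f"scorr_{i}", [f"F{i}", f"G{i}"], mode="centroid_corr",
                centroids={"X": {f"F{i}": 1.0, f"G{i}": -1.0}},
            )
        )
    for i in range(3):
        modules.append(
            ModuleDefinition(
                f"pub_{i}", [f"H{i}"], mode="published_model", weights={f"H{i}": 1.0}
            )
        )
    reg = ModuleRegistry(modules)
    assert len(reg) == 323
    assert reg.counts_by_mode() == {
        "median": 221, "first_pc": 77, "centroid_corr": 22, "published_model": 3
    }
    gmt, sc = tmp_path / "full.gmt", tmp_path / "full.json"
    write_module_registry(reg, gmt, sc)
    back = read_module_registry(gmt, sc)
    assert back.names == reg.names
    for m in reg:
        b = back[m.name]
        assert (b.mode, b.genes, b.centroids, b.weights, b.offset) == (
            m.mode, m.genes, m.centroids, m.weights, m.offset
        )


# ---------------------------------------------------------------------------
# Gene matching


def test_match_genes_full_and_partial(toy_expr):
    full = ModuleDefinition("m", ["ERBB2", "ESR1"], mode="median")
    rep = match_genes(toy_expr, full)
    assert rep.matched == ["ERBB2", "ESR1"] and rep.fraction == 1.0 and rep.scoreable

    sparse = ModuleDefinition("m2", ["ERBB2", "ESR1"] + [f"X{i}" for i in range(8)])
    rep2 = match_genes(toy_expr, sparse, min_fraction=0.5)
    assert not rep2.scoreable and rep2.fraction == pytest.approx(0.2)


def test_match_genes_is_case_insensitive(toy_expr):
    mod = ModuleDefinition("m", ["Erbb2", "esr1"], mode="median")
    rep = match_genes(toy_expr, mod)
    assert rep.matched == ["ERBB2", "ESR1"]


# ---------------------------------------------------------------------------
# Median scoring


def test_median_score_of_single_gene_module_is_centered_row(toy_expr):
    mod = ModuleDefinition("m", ["MKI67"], mode="median")
    score, _ = score_median(toy_expr, mod)
    row = toy_expr.values.loc["MKI67"]
    assert np.allclose(score, row - row.median())


def test_median_score_brute_force_three_genes():
    expr = _expr([[1.0], [2.0], [7.0]], ["A", "B", "C"], ["s1"])
    # single sample: per-gene medians equal the values, centered values are 0
    mod = ModuleDefinition("m", ["A", "B", "C"], mode="median")
    score, _ = score_median(expr, mod)
    assert score["s1"] == 0.0
    # with an explicit zero-median reference the raw medians survive
    ref = _expr([[0.0], [0.0], [0.0]], ["A", "B", "C"], ["r1"])
    score2, _ = score_median(expr, mod, reference=ref)
    assert score2["s1"] == 2.0  # median of (1, 2, 7)


def test_median_score_invariant_to_gene_order_and_identical_profiles():
    vals = np.array([[1.0, 4.0, 2.0]] * 3)
    expr = _expr(vals, ["A", "B", "C"], ["s1", "s2", "s3"])
    m1 = ModuleDefinition("m", ["A", "B", "C"], mode="median")
    m2 = ModuleDefinition("m", ["C", "A", "B"], mode="median")
    s1, _ = score_median(expr, m1)
    s2, _ = score_median(expr, m2)
    assert np.allclose(s1, s2)
    shared = expr.values.loc["A"] - expr.values.loc["A"].median()
    assert np.allclose(s1, shared)


# ---------------------------------------------------------------------------
# First-PC scoring


def test_first_pc_rank_one_case_recovers_shared_profile():
    expr = _expr([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0]], ["A", "B"], ["s1", "s2", "s3"])
    mod = ModuleDefinition("m", ["A", "B"], mode="first_pc")
    score, _ = score_first_pc(expr, mod)
    expected = np.array([-1.0, 0.0, 1.0])
    expected = expected / expected.std(ddof=1)
    assert np.allclose(score, expected, atol=1e-10)
    assert np.corrcoef(score, expr.values.mean(axis=0))[0, 1] > 0


def test_first_pc_matches_dense_eigendecomposition_oracle():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(3, 4))
    expr = _expr(vals, ["A", "B", "C"], list("wxyz"))
    mod = ModuleDefinition("m", ["A", "B", "C"], mode="first_pc")
    score, _ = score_first_pc(expr, mod)
    # oracle: eigendecomposition of the gene-gene covariance of z-scores
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    cov = z @ z.T
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    proj = axis @ z
    if np.dot(proj - proj.mean(), z.mean(axis=0) - z.mean(axis=0).mean()) < 0:
        proj = -proj
    proj = (proj - proj.mean()) / proj.std(ddof=1)
    assert np.allclose(score, proj, atol=1e-8)


def test_first_pc_sign_convention_survives_global_negation():
    rng = np.random.default_rng(9)
    vals = rng.normal(size=(4, 6))
    genes, samples = list("ABCD"), [f"s{i}" for i in range(6)]
    mod = ModuleDefinition("m", genes, mode="first_pc")
    s_pos, _ = score_first_pc(_expr(vals, genes, samples), mod)
    s_neg, _ = score_first_pc(_expr(-vals, genes, samples), mod)
    # orientation ties the score to the mean member profile, which flips too
    assert np.allclose(s_pos, -s_neg, atol=1e-8)


def test_first_pc_drops_zero_variance_gene_with_warning():
    vals = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [0.5, 1.5, 2.5]])
    expr = _expr(vals, ["A", "B", "C"], ["s1", "s2", "s3"])
    mod = ModuleDefinition("m", ["A", "B", "C"], mode="first_pc")
    with pytest.warns(UserWarning, match="zero-variance"):
        score, _ = score_first_pc(expr, mod)
    assert score is not None


# ---------------------------------------------------------------------------
# Centroid-correlation scoring


def test_centroid_correlation_extremes_and_oracle():
    genes = ["A", "B", "C", "D", "E"]
    centroid = {"c1": dict(zip(genes, [1.0, 2.0, 3.0, 4.0, 5.0]))}
    mod = ModuleDefinition("m", genes, mode="centroid_corr", centroids=centroid)
    up = np.array([0.1, 0.5, 1.2, 3.3, 9.0])
    expr = _expr(np.column_stack([up, up[::-1]]), genes, ["same", "reversed"])
    scores, _ = score_centroid_correlation(expr, mod)
    assert scores.loc["m.c1", "same"] == pytest.approx(1.0)
    assert scores.loc["m.c1", "reversed"] == pytest.approx(-1.0)

    # hand-ranked oracle on a tied-free toy profile
    profile = np.array([2.0, 9.0, 1.0, 7.0, 4.0])
    expr2 = _expr(profile[:, None], genes, ["s"])
    scores2, _ = score_centroid_correlation(expr2, mod)
    ranks_p = np.array([2, 5, 1, 4, 3], dtype=float)  # ranks of profile
    ranks_c = np.array([1, 2, 3, 4, 5], dtype=float)
    oracle = np.corrcoef(ranks_p, ranks_c)[0, 1]
    assert scores2.loc["m.c1", "s"] == pytest.approx(oracle, abs=1e-12)


def test_centroid_correlation_constant_profile_is_missing():
    genes = ["A", "B", "C"]
    mod = ModuleDefinition(
        "m", genes, mode="centroid_corr",
        centroids={"c": {"A": 1.0, "B": 2.0, "C": 3.0}},
    )
    expr = _expr(np.array([[5.0], [5.0], [5.0]]), genes, ["s"])
    scores, _ = score_centroid_correlation(expr, mod)
    assert np.isnan(scores.loc["m.c", "s"])


# ---------------------------------------------------------------------------
# Published-model scoring


def test_published_model_dot_product_oracle():
    genes = ["A", "B", "C"]
    vals = np.array([[1.0, 2.0], [3.0, -1.0], [0.5, 4.0]])
    expr = _expr(vals, genes, ["s1", "s2"])
    mod = ModuleDefinition(
        "m", genes, mode="published_model",
        weights={"A": 0.5, "B": -1.0, "C": 2.0}, offset=0.0,
    )
    score, _ = score_published_model(expr, mod)
    expected = np.array([0.5, -1.0, 2.0]) @ vals
    assert np.allclose(score, expected, atol=1e-12)

    zero = ModuleDefinition("z", genes, mode="published_model",
                            weights={g: 0.0 for g in genes}, offset=0.0)
    s0, _ = score_published_model(expr, zero)
    assert np.allclose(s0, 0.0)

    single = ModuleDefinition("one", ["B"], mode="published_model",
                              weights={"B": 1.0}, offset=0.0)
    s1, _ = score_published_model(expr, single)
    assert np.allclose(s1, vals[1])


# ---------------------------------------------------------------------------
# compute_all_scores


def test_compute_all_scores_row_layout_and_report(toy_expr, toy_registry):
    msm = compute_all_scores(toy_expr, toy_registry)
    # centroid module expands to one row per centroid
    assert list(msm.module_names) == [
        "prolif", "pc_mod", "subtype.Her2", "subtype.LumA", "published"
    ] or set(msm.module_names) == {
        "prolif", "pc_mod", "subtype.LumA", "subtype.Her2", "published"
    }
    assert msm.scores.shape[1] == toy_expr.n_samples
    assert msm.report.loc["prolif", "scoreable"]
    assert (msm.report["fraction"] <= 1.0).all()


@pytest.mark.parametrize("mode", ["median", "first_pc", "centroid_corr", "published_model"])
def test_sample_permutation_equivariance(toy_expr, toy_registry, mode):
    reg = ModuleRegistry([m for m in toy_registry if m.mode == mode])
    perm = ["S3", "S5", "S1", "S4", "S2"]
    permuted = toy_expr.subset_samples(perm)
    orig = compute_all_scores(toy_expr, reg)
    swapped = compute_all_scores(permuted, reg)
    pd.testing.assert_frame_equal(orig.scores[perm], swapped.scores, atol=1e-10, rtol=0)


def test_unscoreable_modules_are_absent_but_reported(toy_expr):
    reg = ModuleRegistry([
        ModuleDefinition("good", ["ERBB2", "ESR1"], mode="median"),
        ModuleDefinition("bad", ["NOPE1", "NOPE2"], mode="median"),
    ])
    with pytest.warns(UserWarning, match="no genes matched"):
        msm = compute_all_scores(toy_expr, reg)
    assert list(msm.module_names) == ["good"]
    assert not msm.report.loc["bad", "scoreable"]
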