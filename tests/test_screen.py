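"""Co-expression screen: centring, exclusions, Pearson, ranked results."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.pipeline import Pipeline

import coexscreen as cx
from coexscreen.tables import DATA_COLUMNS


def table_from_cells(cells, value_kind="relative_expression"):
    """cells: list of (strain, condition, timepoint, gene, value)."""
    df = pd.DataFrame(
        [(s, c, t, 1, g, v) for s, c, t, g, v in cells], columns=DATA_COLUMNS)
    return cx.MeasurementTable(data=df, value_kind=value_kind)


# -- mean centring ----------------------------------------------------------


def test_mean_center_divides_by_cell_mean():
    t = table_from_cells([("A", "c", 1.0, "G", 2.0), ("B", "c", 1.0, "G", 4.0),
                          ("C", "c", 1.0, "G", 6.0)])
    fc = cx.mean_center(t)
    got = dict(zip(fc.data["strain"], fc.data["value"]))
    assert got == {"A": 0.5, "B": 1.0, "C": 1.5}
    assert np.mean(list(got.values())) == pytest.approx(1.0, abs=1e-12)


def test_equal_strains_center_to_unity():
    t = table_from_cells([(s, "c", 1.0, "G", 7.3) for s in "ABCD"])
    fc = cx.mean_center(t)
    assert (fc.data["value"] == 1.0).all()


def test_single_strain_cell_yields_missing():
    t = table_from_cells([("A", "c", 1.0, "G", 2.0), ("A", "c", 3.0, "G", 5.0),
                          ("B", "c", 3.0, "G", 5.0)])
    fc = cx.mean_center(t)
    # the lone (c, 1.0) cell disappears; the complete (c, 3.0) cell survives
    assert set(fc.data["timepoint_h"]) == {3.0}


def test_all_zero_cell_yields_missing():
    t = table_from_cells([("A", "c", 1.0, "G", 0.0), ("B", "c", 1.0, "G", 0.0)])
    assert len(cx.mean_center(t)) == 0


def test_centring_invariant_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(100):
        ns, nc, nt, ng = rng.integers(2, 6), rng.integers(1, 4), rng.integers(1, 4), rng.integers(1, 4)
        cells = [
            (f"S{i}", f"c{j}", float(k + 1), f"G{m}", float(rng.lognormal(0, 1)))
            for i in range(ns) for j in range(nc) for k in range(nt) for m in range(ng)
        ]
        fc = cx.mean_center(table_from_cells(cells))
        means = fc.data.groupby(["gene", "condition", "timepoint_h"])["value"].mean()
        assert np.allclose(means, 1.0, rtol=0, atol=1e-12)


# -- log2 -------------------------------------------------------------------


@pytest.mark.parametrize("v,expected", [(1.0, 0.0), (8.0, 3.0), (0.0, -10.0)])
def test_log2_transform_with_floor(v, expected):
    t = table_from_cells([("A", "c", 1.0, "G", v)], value_kind="fold_change")
    out = cx.log2_transform(t, floor=2.0 ** -10)
    assert out.data["value"].iloc[0] == expected


def test_log2_floor_must_be_positive():
    t = table_from_cells([("A", "c", 1.0, "G", 1.0)], value_kind="fold_change")
    with pytest.raises(cx.DomainError, match="floor"):
        cx.log2_transform(t, floor=0.0)


# -- exclusion masks --------------------------------------------------------


def test_exclusion_masks_paper_design(design):
    assert cx.exclusion_mask("CYG56", design) == {"cyg56"}
    assert cx.exclusion_mask("42.49CG1", design) == set()  # strain 42.49 not profiled
    assert cx.exclusion_mask("42.49CG1", design, {"54.10"}) == {"54.10"}
    assert cx.exclusion_mask("CDP1", design, {"54.10"}) == {"cdp1", "54.10"}


def test_exclusion_mask_unknown_gene(design):
    with pytest.raises(cx.VocabularyError, match="NOPE"):
        cx.exclusion_mask("NOPE", design)


# -- pearson core -----------------------------------------------------------


def test_pearson_hand_example():
    res = cx.pearson([1, 2, 3], [1, 3, 2])
    assert res.r == pytest.approx(0.5)
    assert res.r2 == pytest.approx(0.25)
    assert res.n == 3
    # p from the exact t transform on n-2 df
    t = res.r * np.sqrt((res.n - 2) / (1 - res.r2))
    assert res.p == pytest.approx(2 * stats.t.sf(abs(t), res.n - 2))


def test_pearson_perfect_and_negative():
    x = np.arange(1.0, 7.0)
    perfect = cx.pearson(x, 2 * x + 1)
    assert perfect.r == pytest.approx(1.0, abs=1e-12)
    assert perfect.r2 == pytest.approx(1.0, abs=1e-12)
    assert 0 < perfect.p <= 1e-300  # t transform diverges, p underflows to the clamp
    neg = cx.pearson(x, -x)
    assert neg.r == pytest.approx(-1.0, abs=1e-12)
    assert neg.r2 == pytest.approx(1.0, abs=1e-12)
    assert 0 < neg.p <= 1e-300


def test_pearson_degenerate_inputs():
    with pytest.raises(cx.InsufficientDataError):
        cx.pearson([1, 2], [3, 4])
    with pytest.raises(cx.ConstantInputError):
        cx.pearson([1, 1, 1], [1, 2, 3])
    # pairwise-complete filtering happens before the n check
    with pytest.raises(cx.InsufficientDataError):
        cx.pearson([1, 2, np.nan], [1, 2, 3])


# -- full screen ------------------------------------------------------------


def test_sample_counts_follow_exclusion_arithmetic(design, paper_table):
    screen = cx.CoexpressionScreen(design=design).fit(paper_table)
    by_gene = {r.gene: r for r in screen.results_}
    # 144 - 16 reference-mutant samples
    assert by_gene["42.49CG1"].n == 128
    # union exclusion: both own mutants
    assert by_gene["CDP1"].n == 112
    assert by_gene["CDP1"].excluded_strains == ("cdp1", "cyg56")
    assert by_gene["CDP1"].exclusion_reasons["cyg56"] == "own_mutant_of_reference"


def test_leave_strain_out_removes_16_samples(design, paper_table):
    screen = cx.CoexpressionScreen(design=design, leave_out=("54.10",)).fit(paper_table)
    by_gene = {r.gene: r for r in screen.results_}
    assert by_gene["42.49CG1"].n == 112
    assert by_gene["42.49CG1"].exclusion_reasons["54.10"] == "leave_out"


def test_per_gene_exclusion_keeps_reference_mutant(design, paper_table):
    screen = cx.CoexpressionScreen(design=design, pair_exclusion="per_gene").fit(paper_table)
    by_gene = {r.gene: r for r in screen.results_}
    assert by_gene["42.49CG1"].n == 144
    assert by_gene["CDP1"].n == 128  # only cdp1 excluded


def test_reference_control_row_ranks_first(design, paper_table):
    screen = cx.CoexpressionScreen(design=design).fit(paper_table)
    first = screen.results_[0]
    assert first.note == "self" and first.gene == design.reference_gene
    assert first.r2 == 1.0
    r2s = [r.r2 for r in screen.results_ if r.ok]
    assert r2s == sorted(r2s, reverse=True)


def test_planted_artifact_in_own_mutant_changes_nothing(design, paper_table):
    logt = cx.log2_transform(cx.mean_center(paper_table, design))
    base = {r.gene: r for r in cx.correlate_vs_reference(logt, design)}["CDP1"]
    poisoned = logt.data.copy()
    sel = (poisoned["gene"] == "CDP1") & (poisoned["strain"] == "cdp1")
    assert sel.any()
    poisoned.loc[sel, "value"] = 40.0  # extreme log2 artifact
    redo = cx.correlate_vs_reference(logt.with_data(poisoned), design)
    after = {r.gene: r for r in redo}["CDP1"]
    assert after.r == base.r and after.p == base.p and after.n == base.n


def test_constant_gene_becomes_flagged_row_not_abort():
    design = cx.build_design(
        strains=("wt", "m"), wild_type="wt", conditions=("c",), timepoints_h=(1.0, 2.0, 3.0),
        gene_panel=("REF", "FLAT"), reference_gene="REF")
    cells = []
    for i, t in enumerate((1.0, 2.0, 3.0)):
        for j, s in enumerate(("wt", "m")):
            cells.append((s, "c", t, "REF", float(i + j + 1)))
            cells.append((s, "c", t, "FLAT", 0.0))
    table = table_from_cells(cells, value_kind="log2_fold_change")
    res = cx.correlate_vs_reference(table, design)
    flat = [r for r in res if r.gene == "FLAT"][0]
    assert not flat.ok and flat.note == "ConstantInputError"
    assert res[-1] is flat  # undefined rows sort last


def test_screen_matches_bruteforce_on_small_random_tables(design):
    rng = np.random.default_rng(7)
    for _ in range(10):
        check_against_bruteforce(rng)


def check_against_bruteforce(rng):
    ns = int(rng.integers(3, 6))
    strains = tuple(f"S{i}" for i in range(ns))
    genes = ("REF",) + tuple(f"G{i}" for i in range(int(rng.integers(2, 5))))
    mapping = {}
    for g in genes:
        if rng.random() < 0.5:
            mapping[g] = strains[int(rng.integers(0, ns))]
    design = cx.build_design(
        strains=strains, wild_type=strains[0], conditions=("c1", "c2"),
        timepoints_h=(1.0, 2.0), gene_panel=genes, reference_gene="REF",
        gene_to_mutant={g: m for g, m in mapping.items()
                        if len([x for x in mapping.values() if x == m]) == 1})
    rows = []
    for s in strains:
        for c in ("c1", "c2"):
            for t in (1.0, 2.0):
                for g in genes:
                    if rng.random() < 0.9:
                        rows.append((s, c, t, 1, g, float(rng.normal())))
    table = cx.MeasurementTable(data=pd.DataFrame(rows, columns=DATA_COLUMNS),
                                value_kind="log2_fold_change")
    results = {r.gene: r for r in cx.correlate_vs_reference(table, design)}

    # brute force: explicit loops, textbook formulas
    data = {(s, c, t, g): v for s, c, t, _, g, v in rows}
    ref_mut = design.own_mutant("REF")
    for g in genes:
        if g == "REF":
            continue
        excl = {m for m in (design.own_mutant(g), ref_mut) if m is not None}
        xs, ys = [], []
        for s in strains:
            if s in excl:
                continue
            for c in ("c1", "c2"):
                for t in (1.0, 2.0):
                    if (s, c, t, g) in data and (s, c, t, "REF") in data:
                        xs.append(data[(s, c, t, g)])
                        ys.append(data[(s, c, t, "REF")])
        n = len(xs)
        got = results[g]
        assert got.n == n
        if n < 3 or len(set(xs)) == 1 or len(set(ys)) == 1:
            assert not got.ok
            continue
        mx, my = sum(xs) / n, sum(ys) / n
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        sxx = sum((x - mx) ** 2 for x in xs)
        syy = sum((y - my) ** 2 for y in ys)
        r = sxy / np.sqrt(sxx * syy)
        assert got.r == pytest.approx(r, abs=1e-10)
        assert got.r2 == pytest.approx(r * r, abs=1e-10)
        tstat = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(tstat), n - 2)
        assert got.p == pytest.approx(p, rel=1e-8)


def test_recovery_ranks_planted_genes_first(design, paper_table):
    screen = cx.CoexpressionScreen(design=design).fit(paper_table)
    assert set(screen.top_genes(3)) == {"CDP1", "42.49CG1", "85.37CG"}
    # internal control: stable genes sit below every co-regulated gene
    by_gene = {r.gene: r.r2 for r in screen.results_ if r.ok and r.note != "self"}
    stable_max = max(by_gene["20.40CG1"], by_gene["258.90CG"])
    assert stable_max < min(by_gene["CDP1"], by_gene["42.49CG1"], by_gene["85.37CG"])


# -- estimator surface ------------------------------------------------------


def test_estimators_clone_and_compose(design, paper_table):
    pipe = Pipeline([("center", cx.CellMeanCenterer()), ("log2", cx.Log2FoldChange())])
    logt = pipe.fit_transform(paper_table)
    assert logt.value_kind == "log2_fold_change"
    screen = cx.CoexpressionScreen(design=design, leave_out=("54.10",))
    cloned = clone(screen)
    assert cloned.get_params()["leave_out"] == ("54.10",)
    res_direct = screen.fit(paper_table).results_frame_
    res_staged = cloned.fit(logt).results_frame_
    pd.testing.assert_frame_equal(res_direct, res_staged)


def test_screen_requires_design_and_table(paper_table, design):
    with pytest.raises(cx.DomainError, match="design"):
        cx.CoexpressionScreen().fit(paper_table)
    with pytest.raises(cx.DomainError, match="MeasurementTable"):
        cx.CoexpressionScreen(design=design).fit(paper_table.data)
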