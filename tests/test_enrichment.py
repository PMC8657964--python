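import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mptriage.enrichment import (
    GoDag,
    build_dag,
    deepest_terms,
    fisher_term_test,
    load_ontology,
    make_random_dag,
    nested_inclusive_analysis,
    propagate_annotations,
    records_table,
)

from oracles import closure_oracle, fisher_two_sided_oracle

TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: branch one
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: leaf of branch one
namespace: biological_process
is_a: GO:0000002 ! branch one

[Term]
id: GO:0000004
name: diamond term
namespace: biological_process
is_a: GO:0000003 ! leaf of branch one
relationship: part_of GO:0000002 ! branch one

[Term]
id: GO:0000005
name: obsolete thing
namespace: biological_process
is_obsolete: true

[Term]
id: GO:0000010
name: cc root
namespace: cellular_component
"""


@pytest.fixture()
def toy_dag(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return load_ontology(str(p))


def test_obo_chain_levels(toy_dag):
    assert toy_dag.levels["GO:0000001"] == 1
    assert toy_dag.levels["GO:0000002"] == 2
    assert toy_dag.levels["GO:0000003"] == 3


def test_diamond_term_gets_shortest_path_level(toy_dag):
    # parents at level 3 (is_a) and level 2 (part_of): shortest path wins
    assert toy_dag.levels["GO:0000004"] == 3


def test_obsolete_terms_skipped_and_stanza_count(tmp_path, toy_dag):
    assert "GO:0000005" not in toy_dag.names
    # independent stanza count: non-obsolete [Term] stanzas
    stanzas = TOY_OBO.split("[Term]")[1:]
    live = sum(1 for s in stanzas if "is_obsolete: true" not in s)
    assert len(toy_dag.names) == live


def test_namespaces_and_roots(toy_dag):
    assert toy_dag.roots == {"BP": "GO:0000001", "CC": "GO:0000010"}
    assert toy_dag.namespaces["GO:0000004"] == "BP"


def test_cyclic_ontology_rejected():
    names = {"a": "a", "b": "b"}
    ns = {"a": "BP", "b": "BP"}
    with pytest.raises(ValueError, match="cycle"):
        build_dag(names, ns, {"a": ["b"], "b": ["a"]})


def test_rootless_namespace_rejected():
    # every term has a parent inside the namespace -> no root
    names = {"a": "a", "b": "b", "c": "c"}
    ns = {"a": "BP", "b": "BP", "c": "CC"}
    with pytest.raises(ValueError, match="no root|multiple roots|cycle"):
        build_dag(names, ns, {"a": ["b"], "b": ["a"], "c": []})


# -- annotation propagation --------------------------------------------------


def test_leaf_annotation_propagates_to_all_ancestors(toy_dag):
    annot, skipped = propagate_annotations({"gene1": {"GO:0000004"}}, toy_dag)
    assert annot["gene1"] == {"GO:0000004", "GO:0000003", "GO:0000002", "GO:0000001"}
    assert skipped == 0


def test_root_annotation_is_fixed_point(toy_dag):
    annot, _ = propagate_annotations({"gene1": {"GO:0000001"}}, toy_dag)
    assert annot["gene1"] == {"GO:0000001"}


def test_unknown_terms_skipped_and_counted(toy_dag):
    annot, skipped = propagate_annotations(
        {"g": {"GO:9999999", "GO:0000002"}}, toy_dag
    )
    assert skipped == 1
    assert annot["g"] == {"GO:0000002", "GO:0000001"}


def test_propagation_matches_transitive_closure_oracle(rng):
    dag = make_random_dag(60, rng)
    genes = {f"g{i}": set(rng.choice(list(dag.names), size=3, replace=False))
             for i in range(30)}
    annot, _ = propagate_annotations(genes, dag)
    for g, terms in genes.items():
        assert annot[g] == closure_oracle(terms, dag.parents)


def test_annotation_counts_monotone_up_the_dag(rng):
    dag = make_random_dag(80, rng)
    genes = {f"g{i}": set(rng.choice(list(dag.names), size=2, replace=False))
             for i in range(50)}
    annot, _ = propagate_annotations(genes, dag)
    counts = {t: sum(t in a for a in annot.values()) for t in dag.names}
    for child, parents in dag.parents.items():
        for p in parents:
            assert counts[p] >= counts[child]


# -- Fisher's exact test -----------------------------------------------------


def _dag_one_term():
    return build_dag({"root": "root", "T": "t"}, {"root": "BP", "T": "BP"},
                     {"root": [], "T": ["root"]})


def _fisher_p(k_class, n_class, k_rog, n_rog):
    dag = _dag_one_term()
    class_genes = [f"c{i}" for i in range(n_class)]
    rog_genes = [f"r{i}" for i in range(n_rog)]
    annot = {g: frozenset({"T", "root"}) for g in class_genes[:k_class]}
    annot.update({g: frozenset({"T", "root"}) for g in rog_genes[:k_rog]})
    rec = fisher_term_test(class_genes, rog_genes, "T", annot, dag)
    assert (rec.k_class, rec.n_class, rec.k_rog, rec.n_rog) == (
        k_class, n_class, k_rog, n_rog)
    return rec.p


def test_fisher_matches_enumeration_on_spec_tables():
    assert _fisher_p(5, 100, 10, 9900) == pytest.approx(
        fisher_two_sided_oracle(5, 95, 10, 9890), abs=1e-10
    )
    # equal odds, small counts: two-sided p = 1
    assert _fisher_p(1, 10, 10, 100) == pytest.approx(
        fisher_two_sided_oracle(1, 9, 10, 90), abs=1e-10
    )
    assert fisher_two_sided_oracle(1, 9, 10, 90) == pytest.approx(1.0, abs=1e-9)


def test_fisher_extreme_table_is_minimal_p():
    # whole class annotated, nothing in ROG: the most extreme table
    p_obs = _fisher_p(6, 6, 0, 40)
    for k in range(6):
        assert p_obs <= _fisher_p(k, 6, 6 - k, 40)


def test_fisher_rejects_bad_inputs():
    dag = _dag_one_term()
    with pytest.raises(ValueError, match="empty"):
        fisher_term_test([], ["r1"], "T", {}, dag)
    with pytest.raises(ValueError, match="overlap"):
        fisher_term_test(["x"], ["x"], "T", {}, dag)


def test_fisher_matches_oracle_on_random_tables(rng):
    for _ in range(150):
        a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
        if a + b == 0 or c + d == 0:
            continue
        got = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert got == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-10)


# -- nested inclusive analysis ----------------------------------------------


def _chain_dag(depth=6):
    names = {f"T{i}": f"t{i}" for i in range(depth)}
    ns = {t: "BP" for t in names}
    parents = {f"T{i}": [f"T{i - 1}"] if i else [] for i in range(depth)}
    return build_dag(names, ns, parents)


def test_chain_reports_only_deepest_term():
    """Class genes all carrying the chain tip: only the tip is 'deepest'."""
    dag = _chain_dag(6)  # levels 1..6
    class_genes = [f"c{i}" for i in range(20)]
    rog_genes = [f"r{i}" for i in range(400)]
    annot = {g: frozenset(dag.names) for g in class_genes}  # tip + ancestors
    annot.update({g: frozenset({"T0"}) for g in rog_genes})
    records = nested_inclusive_analysis(class_genes, rog_genes, dag, annot,
                                        levels=range(3, 10))
    deep = deepest_terms(records)
    assert [r.term_id for r in deep] == ["T5"]
    sig = [r for r in records if r.fdr_p <= 0.05]
    assert {r.term_id for r in sig} == {"T2", "T3", "T4", "T5"}


def test_deepest_terms_form_antichain(rng):
    dag = make_random_dag(150, rng)
    all_terms = list(dag.names)
    genes = {f"g{i}": set(rng.choice(all_terms, size=4, replace=False))
             for i in range(300)}
    annot, _ = propagate_annotations(genes, dag)
    gene_ids = list(genes)
    for _ in range(5):
        cls = set(rng.choice(gene_ids, size=40, replace=False))
        # enrich the class towards one term's carriers to force significance
        target = all_terms[int(rng.integers(1, len(all_terms)))]
        carriers = [g for g in gene_ids if target in annot[g]]
        cls |= set(carriers[:30])
        rog = set(gene_ids) - cls
        records = nested_inclusive_analysis(cls, rog, dag, annot, levels=range(2, 10),
                                            alpha=0.2)
        deep = {r.term_id for r in deepest_terms(records)}
        for t in deep:
            assert not (dag.ancestors(t) & deep)
            assert not (dag.descendants(t) & deep)


def test_null_class_rarely_significant(rng):
    dag = make_random_dag(100, rng)
    all_terms = list(dag.names)
    genes = {f"g{i}": set(rng.choice(all_terms, size=3, replace=False))
             for i in range(400)}
    annot, _ = propagate_annotations(genes, dag)
    gene_ids = list(genes)
    n_deep = []
    for _ in range(20):
        cls = set(rng.choice(gene_ids, size=40, replace=False))
        records = nested_inclusive_analysis(cls, set(gene_ids) - cls, dag, annot,
                                            levels=range(3, 10), alpha=0.05)
        n_deep.append(len(deepest_terms(records)))
    # random classes: significant deepest terms are rare
    assert np.mean(n_deep) <= 0.5


def test_empty_level_range_rejected(toy_dag):
    with pytest.raises(ValueError, match="empty"):
        nested_inclusive_analysis({"g"}, {"h"}, toy_dag, {}, levels=())


def test_bh_within_level_monotone(rng):
    dag = make_random_dag(120, rng)
    all_terms = list(dag.names)
    genes = {f"g{i}": set(rng.choice(all_terms, size=4, replace=False))
             for i in range(200)}
    annot, _ = propagate_annotations(genes, dag)
    gene_ids = list(genes)
    cls = set(rng.choice(gene_ids, size=50, replace=False))
    records = nested_inclusive_analysis(cls, set(gene_ids) - cls, dag, annot,
                                        levels=range(2, 10), alpha=0.05)
    df = records_table(records)
    for level, sub in df.groupby("level"):
        sub = sub.sort_values("p")
        assert (sub["fdr_p"].diff().dropna() >= -1e-12).all()


def test_records_table_shape(toy_dag):
    annot, _ = propagate_annotations({"g1": {"GO:0000004"}, "g2": {"GO:0000002"}},
                                     toy_dag)
    records = nested_inclusive_analysis({"g1"}, {"g2"}, toy_dag, annot,
                                        levels=range(2, 10))
    df = records_table(records)
    assert {"term_id", "level", "k_class", "p", "fdr_p", "deepest"} <= set(df.columns)
    assert (df["k_class"] <= df["n_class"]).all()
    assert df["p"].between(0, 1).all()
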