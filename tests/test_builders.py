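"""Network builders: planted enrichment, restriction rules, sign
classification and regulation-source accounting, with a hand-enumerated
join oracle for the metabolic builder."""

import itertools

import pandas as pd
import pytest

from transnetkit import fixtures
from transnetkit.builders import (
    BuildConfig,
    RegulatorRole,
    build_exchange_network,
    build_gene_regulatory_network,
    build_metabolic_network,
    build_ppi_network,
    classify_regulation_sign,
    classify_regulation_source,
)
from transnetkit.graph_core import (
    Compartment,
    Direction,
    EdgeType,
    Layer,
    Sign,
    validate_network,
)
from transnetkit.kb_readers import KnowledgeBase
from transnetkit.omics_io import OmicsTable
from transnetkit.stats import ContingencyTable, fisher_exact_one_tailed


def _empty(columns):
    return pd.DataFrame(columns=columns)


def make_kb(**tables) -> KnowledgeBase:
    defaults = {
        "tf_targets": _empty(["experiment_id", "tf_name", "target_gene", "binding_score", "tss_window_kb"]),
        "mirna_targets": _empty(["mirna_id", "target_gene", "support_type"]),
        "ppi_links": _empty(["protein_a", "protein_b", "combined_score"]),
        "reactions": _empty(["reaction_id", "ec_number", "gene", "compound_id", "role", "pathway_id"]),
        "allosteric": _empty(["ec_number", "compound_id", "mode", "ambiguous"]),
        "transporters": _empty(["transporter_id", "gene", "compound_id", "chebi_degree", "membrane_localized"]),
    }
    defaults.update(tables)
    return KnowledgeBase(**defaults)


def mrna_table(records, compartment=Compartment.TISSUE):
    return OmicsTable(Layer.MRNA, compartment, records, "test")


def metab_table(records, compartment=Compartment.TISSUE):
    return OmicsTable(Layer.METABOLITE, compartment, records, "test")


# ---------------------------------------------------------------------------
# sign rules
# ---------------------------------------------------------------------------

ACTIVATING_CELLS = {
    (RegulatorRole.ENZYME_MRNA, Direction.INCREASED),
    (RegulatorRole.SUBSTRATE, Direction.INCREASED),
    (RegulatorRole.PRODUCT, Direction.DECREASED),
    (RegulatorRole.ALLOSTERIC_ACTIVATOR, Direction.INCREASED),
    (RegulatorRole.ALLOSTERIC_INHIBITOR, Direction.DECREASED),
    (RegulatorRole.TRANSPORTER_MRNA, Direction.INCREASED),
    (RegulatorRole.TRANSPORT_SUBSTRATE, Direction.INCREASED),
}


class TestSignRules:
    @pytest.mark.parametrize(
        "role,direction",
        list(itertools.product(list(RegulatorRole), [Direction.INCREASED, Direction.DECREASED])),
    )
    def test_truth_table(self, role, direction):
        expected = (
            Sign.ACTIVATING if (role, direction) in ACTIVATING_CELLS else Sign.INHIBITING
        )
        assert classify_regulation_sign(role, direction) is expected

    def test_exactly_seven_cells_activate(self):
        cells = [
            classify_regulation_sign(r, d)
            for r in RegulatorRole
            for d in (Direction.INCREASED, Direction.DECREASED)
        ]
        assert cells.count(Sign.ACTIVATING) == 7
        assert cells.count(Sign.INHIBITING) == 7

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            classify_regulation_sign(RegulatorRole.SUBSTRATE, Direction.UNKNOWN)


# ---------------------------------------------------------------------------
# A. gene regulatory network
# ---------------------------------------------------------------------------

class TestGeneRegulatory:
    def test_planted_tf_is_uniquely_enriched_and_wired(self, planted_dir):
        spec = fixtures.FixtureSpec(seed=5, planted_tf=fixtures.PlantedEnrichment())
        truth = fixtures.generate_omics_with_planted_enrichment(spec, planted_dir)
        kb = fixtures.load_planted_enrichment_kb(planted_dir)
        mrna = mrna_table([(g, Direction.INCREASED) for g in truth["de_genes"]])
        bg = set(pd.read_csv(planted_dir / "background_genes.txt", header=None)[0])
        net, results = build_gene_regulatory_network(mrna, kb, bg)

        significant = {r.experiment_id for r in results if r.q_value <= 0.05}
        assert significant == {"EXP_PLANTED"}
        # Fisher p on the planted table verified against the stated contingency
        planted = next(r for r in results if r.experiment_id == "EXP_PLANTED")
        ct = truth["contingency"]
        expected_p = fisher_exact_one_tailed(
            ContingencyTable(ct["a"], ct["b"], ct["c"], ct["d"])
        )
        assert planted.p_value == pytest.approx(expected_p, abs=1e-14)
        edges = {e.target[0] for e in net.edges if e.edge_type is EdgeType.TF_TARGET}
        assert edges == set(truth["expected_edges"])
        assert validate_network(net) == []

    def test_vacuous_fdr_threshold_admits_every_overlapping_experiment(self):
        tf_rows = pd.DataFrame(
            [
                ("E1", "TFA", "G1", 10, 1),
                ("E2", "TFB", "G2", 10, 1),
                ("E3", "TFC", "G9", 10, 1),  # no changed target
            ],
            columns=["experiment_id", "tf_name", "target_gene", "binding_score", "tss_window_kb"],
        )
        kb = make_kb(tf_targets=tf_rows)
        mrna = mrna_table([("G1", Direction.INCREASED), ("G2", Direction.INCREASED)])
        bg = {f"G{i}" for i in range(1, 11)}
        net, _ = build_gene_regulatory_network(
            mrna, kb, bg, BuildConfig(fdr_threshold=1.0)
        )
        tf_nodes = {m.id for m in net.nodes if m.layer is Layer.TF}
        assert tf_nodes == {"TFA", "TFB"}

    def test_mirna_without_changed_targets_absent(self):
        mirna_rows = pd.DataFrame(
            [("miR-1", "G1", "f"), ("miR-2", "G9", "f")],
            columns=["mirna_id", "target_gene", "support_type"],
        )
        kb = make_kb(mirna_targets=mirna_rows)
        mrna = mrna_table([("G1", Direction.INCREASED)])
        net, _ = build_gene_regulatory_network(mrna, kb, {"G1", "G9", "G5"})
        mirnas = {m.id for m in net.nodes if m.layer is Layer.MIRNA}
        assert mirnas == {"miR-1"}

    def test_background_missing_uploaded_gene_is_an_error(self):
        mrna = mrna_table([("G1", Direction.INCREASED)])
        with pytest.raises(ValueError, match="background"):
            build_gene_regulatory_network(mrna, make_kb(), {"G2"})

    def test_empty_mrna_table_is_an_error(self):
        with pytest.raises(ValueError):
            build_gene_regulatory_network(mrna_table([]), make_kb(), {"G1"})


# ---------------------------------------------------------------------------
# B. PPI network
# ---------------------------------------------------------------------------

PPI_ROWS = pd.DataFrame(
    [("A", "B", 500), ("B", "D", 900), ("A", "C", 300)],
    columns=["protein_a", "protein_b", "combined_score"],
)


class TestPpiNetwork:
    def test_edges_restricted_to_uploaded_pairs(self):
        kb = make_kb(ppi_links=PPI_ROWS)
        mols = mrna_table(
            [("A", Direction.INCREASED), ("B", Direction.INCREASED), ("C", Direction.DECREASED)]
        )
        net = build_ppi_network(mols, kb)
        ids = {m.id for m in net.nodes}
        assert ids == {"A", "B", "C"}  # D not uploaded; C isolated but in KB
        pairs = {(e.source[0], e.target[0]) for e in net.edges}
        assert pairs == {("A", "B")}
        assert validate_network(net) == []

    def test_neighbor_expansion_flag_pulls_in_kb_partners(self):
        kb = make_kb(ppi_links=PPI_ROWS)
        mols = mrna_table([("B", Direction.INCREASED)])
        net = build_ppi_network(mols, kb, BuildConfig(include_ppi_neighbors=True))
        ids = {m.id for m in net.nodes}
        assert ids == {"A", "B", "D"}
        assert net.get_node(("D", Layer.MRNA, Compartment.TISSUE)).direction is Direction.UNKNOWN

    def test_threshold_above_all_scores_gives_edgeless_network(self):
        kb = make_kb(ppi_links=PPI_ROWS)
        mols = mrna_table([("A", Direction.INCREASED), ("B", Direction.DECREASED)])
        net = build_ppi_network(mols, kb, BuildConfig(ppi_score_threshold=1000))
        assert net.n_edges == 0 and net.n_nodes == 2

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            build_ppi_network(mrna_table([]), make_kb(ppi_links=PPI_ROWS))


# ---------------------------------------------------------------------------
# C. metabolic network — planted toy KB vs hand-enumerated oracle
# ---------------------------------------------------------------------------

REACTION_ROWS = pd.DataFrame(
    [
        # R1: substrates C1, C2; product C3; gene Ga (ec 1.1.1.1)
        ("R1", "1.1.1.1", "", "C1", "substrate", "p1"),
        ("R1", "1.1.1.1", "", "C2", "substrate", "p1"),
        ("R1", "1.1.1.1", "", "C3", "product", "p1"),
        ("R1", "1.1.1.1", "Ga", "", "", "p1"),
        # R2: substrate C3; product C4; gene Gb (ec 2.2.2.2)
        ("R2", "2.2.2.2", "", "C3", "substrate", "p1"),
        ("R2", "2.2.2.2", "", "C4", "product", "p1"),
        ("R2", "2.2.2.2", "Gb", "", "", "p1"),
        # R3: substrate C5; product C6; gene Gc — untouched by omics
        ("R3", "3.3.3.3", "", "C5", "substrate", "p2"),
        ("R3", "3.3.3.3", "", "C6", "product", "p2"),
        ("R3", "3.3.3.3", "Gc", "", "", "p2"),
    ],
    columns=["reaction_id", "ec_number", "gene", "compound_id", "role", "pathway_id"],
)

ALLOSTERIC_ROWS = pd.DataFrame(
    [
        ("2.2.2.2", "C1", "inhibitor", False),
        ("1.1.1.1", "C4", "activator", False),
    ],
    columns=["ec_number", "compound_id", "mode", "ambiguous"],
)

# changed molecules: Ga up, C1 up, C3 down
METAB_KB = dict(reactions=REACTION_ROWS, allosteric=ALLOSTERIC_ROWS)

# hand enumeration of (source id, reaction, edge type, sign):
METABOLIC_ORACLE = {
    ("Ga", "R1", EdgeType.ENZYME_MRNA, Sign.ACTIVATING),      # enzyme mRNA up
    ("C1", "R1", EdgeType.SUBSTRATE, Sign.ACTIVATING),        # substrate up
    ("C3", "R1", EdgeType.PRODUCT, Sign.ACTIVATING),          # product down
    ("C3", "R2", EdgeType.SUBSTRATE, Sign.INHIBITING),        # substrate down
    ("C1", "R2", EdgeType.ALLOSTERIC_INHIBITION, Sign.INHIBITING),  # inhibitor up
}


class TestMetabolicNetwork:
    def _build(self):
        kb = make_kb(**METAB_KB)
        mrna = mrna_table([("Ga", Direction.INCREASED)])
        metab = metab_table([("C1", Direction.INCREASED), ("C3", Direction.DECREASED)])
        return build_metabolic_network(mrna, metab, kb)

    def test_edge_list_matches_hand_enumeration(self):
        net = self._build()
        got = {(e.source[0], e.target[0], e.edge_type, e.sign) for e in net.edges}
        assert got == METABOLIC_ORACLE
        assert validate_network(net) == []

    def test_untouched_reaction_absent(self):
        net = self._build()
        assert not net.has_node(("R3", Layer.REACTION, Compartment.NONE))

    def test_metabolite_in_two_roles_yields_two_edge_types(self):
        net = self._build()
        c1_edges = {
            (e.target[0], e.edge_type)
            for e in net.edges_incident(("C1", Layer.METABOLITE, Compartment.TISSUE))
        }
        assert c1_edges == {("R1", EdgeType.SUBSTRATE), ("R2", EdgeType.ALLOSTERIC_INHIBITION)}

    def test_reaction_nodes_carry_pathway_id(self):
        net = self._build()
        assert net.get_node(("R1", Layer.REACTION, Compartment.NONE)).pathway_id == "p1"

    def test_rebuild_is_deterministic(self):
        assert self._build() == self._build()

    def test_adding_a_changed_molecule_is_monotone(self):
        base = self._build()
        kb = make_kb(**METAB_KB)
        mrna = mrna_table([("Ga", Direction.INCREASED), ("Gc", Direction.DECREASED)])
        metab = metab_table([("C1", Direction.INCREASED), ("C3", Direction.DECREASED)])
        bigger = build_metabolic_network(mrna, metab, kb)
        assert base.node_keys <= bigger.node_keys
        assert {e.key for e in base.edges} <= {e.key for e in bigger.edges}

    def test_both_tables_empty_is_an_error(self):
        with pytest.raises(ValueError):
            build_metabolic_network(mrna_table([]), metab_table([]), make_kb(**METAB_KB))

    def test_non_tissue_metabolites_rejected(self):
        with pytest.raises(ValueError):
            build_metabolic_network(
                mrna_table([("Ga", Direction.INCREASED)]),
                metab_table([("C1", Direction.INCREASED)], Compartment.BLOOD),
                make_kb(**METAB_KB),
            )


# ---------------------------------------------------------------------------
# D. exchange network
# ---------------------------------------------------------------------------

TRANSPORTER_ROWS = pd.DataFrame(
    [
        ("TC1", "Aqp7", "glycerol", 5, True),
        ("TC2", "Slc2a1", "glucose", 8, True),
        ("TC3", "Slc7a5", "leucine", 9, True),  # untouched
    ],
    columns=["transporter_id", "gene", "compound_id", "chebi_degree", "membrane_localized"],
)


class TestExchangeNetwork:
    def _build(self):
        kb = make_kb(transporters=TRANSPORTER_ROWS)
        mrna = mrna_table([("Aqp7", Direction.INCREASED)])
        tissue = metab_table([("glucose", Direction.DECREASED)])
        blood = metab_table(
            [("glycerol", Direction.INCREASED), ("glucose", Direction.INCREASED)],
            Compartment.BLOOD,
        )
        return build_exchange_network(mrna, tissue, blood, kb)

    def test_blood_substrate_and_mrna_edges(self):
        net = self._build()
        got = {(e.source[0], e.source[2], e.target[0], e.edge_type, e.sign) for e in net.edges}
        assert got == {
            ("Aqp7", Compartment.TISSUE, "TC1", EdgeType.TRANSPORTER_MRNA, Sign.ACTIVATING),
            ("glycerol", Compartment.BLOOD, "TC1", EdgeType.TRANSPORT_SUBSTRATE, Sign.ACTIVATING),
            ("glucose", Compartment.TISSUE, "TC2", EdgeType.TRANSPORT_SUBSTRATE, Sign.INHIBITING),
            ("glucose", Compartment.BLOOD, "TC2", EdgeType.TRANSPORT_SUBSTRATE, Sign.ACTIVATING),
        }
        assert validate_network(net) == []

    def test_untouched_transporter_absent(self):
        net = self._build()
        assert not net.has_node(("TC3", Layer.TRANSPORTER, Compartment.NONE))

    def test_metabolite_changed_in_both_compartments_is_two_nodes(self):
        net = self._build()
        assert net.has_node(("glucose", Layer.METABOLITE, Compartment.TISSUE))
        assert net.has_node(("glucose", Layer.METABOLITE, Compartment.BLOOD))

    def test_all_inputs_empty_is_an_error(self):
        with pytest.raises(ValueError):
            build_exchange_network(
                mrna_table([]),
                metab_table([]),
                metab_table([], Compartment.BLOOD),
                make_kb(transporters=TRANSPORTER_ROWS),
            )


# ---------------------------------------------------------------------------
# regulation-source classification
# ---------------------------------------------------------------------------

class TestRegulationSource:
    def test_counts_on_planted_toy_net_match_hand_enumeration(self):
        kb = make_kb(**METAB_KB)
        mrna = mrna_table([("Ga", Direction.INCREASED)])
        metab = metab_table([("C1", Direction.INCREASED), ("C3", Direction.DECREASED)])
        net = build_metabolic_network(mrna, metab, kb)
        summary = classify_regulation_source(net)
        # R1: enzyme mRNA + metabolites -> both; R2: metabolites only
        assert summary.n_both == 1
        assert summary.n_metabolite_only == 1
        assert summary.n_mrna_only == 0
        assert summary.n_regulated == 2

    def test_partition_invariant_on_exchange_net(self):
        kb = make_kb(transporters=TRANSPORTER_ROWS)
        net = build_exchange_network(
            mrna_table([("Aqp7", Direction.INCREASED)]),
            metab_table([]),
            metab_table([("glucose", Direction.INCREASED)], Compartment.BLOOD),
            kb,
        )
        summary = classify_regulation_source(net)
        n_centers = sum(1 for m in net.nodes if m.layer is Layer.TRANSPORTER)
        assert summary.n_regulated == n_centers == 2
        assert summary.n_mrna_only == 1 and summary.n_metabolite_only == 1

    def test_network_without_centers_is_an_error(self):
        kb = make_kb(ppi_links=PPI_ROWS)
        net = build_ppi_network(mrna_table([("A", Direction.INCREASED)]), kb)
        with pytest.raises(ValueError):
            classify_regulation_source(net)
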