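"""Builders for the four trans-omics network types.

A. Gene regulatory network: TFs whose ChIP target-gene sets are enriched
   for changed mRNAs (one-tailed Fisher + BH FDR) and miRNAs with at least
   one changed target, with edges regulator → changed mRNA.
B. Protein(mRNA)–protein(mRNA) interaction network from high-confidence
   PPI links between uploaded molecules.
C. Metabolic network: reactions touched by changed enzyme mRNAs or by
   changed metabolites acting as substrates, products or allosteric
   regulators, with each edge classified as activating or inhibiting.
D. Metabolite exchange network: membrane transporters touched by changed
   transporter mRNAs or by changed substrate metabolites in tissue or
   blood, with the same sign classification.

Sign rules (builders C/D): an increased enzyme mRNA, increased substrate,
decreased product, increased allosteric activator and decreased allosteric
inhibitor all activate a reaction; increased transporter mRNAs and
increased substrate metabolites activate a transporter.  Every other
(role, direction) combination inhibits.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Set, Tuple

from .graph_core import (
    Compartment,
    Direction,
    EdgeType,
    Layer,
    Molecule,
    RegulationEdge,
    Sign,
    TransOmicsNetwork,
)
from .kb_readers import KnowledgeBase
from .omics_io import OmicsTable
from .stats import (
    ContingencyTable,
    EnrichmentResult,
    benjamini_hochberg,
    fisher_exact_one_tailed,
)

__all__ = [
    "BuildConfig",
    "RegulatorRole",
    "RegulationSourceSummary",
    "classify_regulation_sign",
    "build_gene_regulatory_network",
    "build_ppi_network",
    "build_metabolic_network",
    "build_exchange_network",
    "classify_regulation_source",
]


class EnrichmentMode(str, enum.Enum):
    JOINT = "joint"
    SPLIT_BY_DIRECTION = "split_by_direction"


@dataclass(frozen=True)
class BuildConfig:
    """Thresholds shared by the builders.

    Defaults follow the source databases' conventions: PPI combined score
    400 ("medium confidence"), transporter-substrate promiscuity cutoff 50
    compounds, FDR 0.05.
    """

    fdr_threshold: float = 0.05
    tf_score_threshold: float = 0.0
    ppi_score_threshold: int = 400
    max_compound_degree: int = 50
    enrichment_mode: EnrichmentMode = EnrichmentMode.SPLIT_BY_DIRECTION
    include_ppi_neighbors: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if not (0 <= self.ppi_score_threshold <= 1000):
            raise ValueError("ppi_score_threshold must be in [0, 1000]")
        if self.max_compound_degree < 1:
            raise ValueError("max_compound_degree must be positive")
        object.__setattr__(self, "enrichment_mode", EnrichmentMode(self.enrichment_mode))


class RegulatorRole(str, enum.Enum):
    """Role a changed molecule plays towards a reaction or transporter."""

    ENZYME_MRNA = "enzyme_mrna"
    SUBSTRATE = "substrate"
    PRODUCT = "product"
    ALLOSTERIC_ACTIVATOR = "allosteric_activator"
    ALLOSTERIC_INHIBITOR = "allosteric_inhibitor"
    TRANSPORTER_MRNA = "transporter_mrna"
    TRANSPORT_SUBSTRATE = "transport_substrate"


#: (role, direction) pairs assumed to ACTIVATE the reaction/transporter.
_ACTIVATING = {
    (RegulatorRole.ENZYME_MRNA, Direction.INCREASED),
    (RegulatorRole.SUBSTRATE, Direction.INCREASED),
    (RegulatorRole.PRODUCT, Direction.DECREASED),
    (RegulatorRole.ALLOSTERIC_ACTIVATOR, Direction.INCREASED),
    (RegulatorRole.ALLOSTERIC_INHIBITOR, Direction.DECREASED),
    (RegulatorRole.TRANSPORTER_MRNA, Direction.INCREASED),
    (RegulatorRole.TRANSPORT_SUBSTRATE, Direction.INCREASED),
}

_ROLE_EDGE_TYPE = {
    RegulatorRole.ENZYME_MRNA: EdgeType.ENZYME_MRNA,
    RegulatorRole.SUBSTRATE: EdgeType.SUBSTRATE,
    RegulatorRole.PRODUCT: EdgeType.PRODUCT,
    RegulatorRole.ALLOSTERIC_ACTIVATOR: EdgeType.ALLOSTERIC_ACTIVATION,
    RegulatorRole.ALLOSTERIC_INHIBITOR: EdgeType.ALLOSTERIC_INHIBITION,
    RegulatorRole.TRANSPORTER_MRNA: EdgeType.TRANSPORTER_MRNA,
    RegulatorRole.TRANSPORT_SUBSTRATE: EdgeType.TRANSPORT_SUBSTRATE,
}


def classify_regulation_sign(role: RegulatorRole, direction: Direction) -> Sign:
    """Differential-regulation sign for a (regulator role, response
    direction) pair; see the module docstring for the rule table."""
    role = RegulatorRole(role)
    direction = Direction(direction)
    if direction not in (Direction.INCREASED, Direction.DECREASED):
        raise ValueError(
            "sign classification requires a measured direction (increased/decreased)"
        )
    return Sign.ACTIVATING if (role, direction) in _ACTIVATING else Sign.INHIBITING


# ---------------------------------------------------------------------------
# A. gene regulatory network
# ---------------------------------------------------------------------------

def build_gene_regulatory_network(
    mrna: OmicsTable,
    kb: KnowledgeBase,
    background: Set[str],
    cfg: BuildConfig = BuildConfig(),
) -> Tuple[TransOmicsNetwork, list[EnrichmentResult]]:
    """TF/miRNA → mRNA network from changed mRNAs.

    For each ChIP experiment the 2x2 table (target × changed, over the
    background) is tested with a one-tailed Fisher's exact test; q-values
    come from a single BH pass over all experiment/direction tests.
    Experiments with q <= ``cfg.fdr_threshold`` contribute a TF node and
    ``tf_target`` edges to their changed target genes only.  miRNAs need no
    test: any miRNA with at least one changed target contributes
    ``mirna_target`` edges.
    """
    if mrna.layer is not Layer.MRNA:
        raise ValueError("gene regulatory builder expects an mRNA table")
    if not mrna.records:
        raise ValueError("mRNA table is empty")
    background = set(background)
    missing = mrna.ids - background
    if missing:
        raise ValueError(
            f"background must contain every uploaded mRNA; missing: {sorted(missing)[:10]}"
        )

    if cfg.enrichment_mode is EnrichmentMode.JOINT:
        de_sets = {"joint": mrna.ids}
    else:
        de_sets = {
            "increased": mrna.ids_with(Direction.INCREASED),
            "decreased": mrna.ids_with(Direction.DECREASED),
        }
        de_sets = {k: v for k, v in de_sets.items() if v}

    results: list[EnrichmentResult] = []
    experiment_targets: dict[str, tuple[str, Set[str]]] = {}
    for (experiment_id, tf_name), rows in kb.tf_targets.groupby(
        ["experiment_id", "tf_name"], sort=True
    ):
        targets = set(rows["target_gene"]) & background
        experiment_targets[str(experiment_id)] = (str(tf_name), targets)
        for label, de in sorted(de_sets.items()):
            a = len(de & targets)
            b = len(de - targets)
            c = len(targets - de)
            d = len(background) - a - b - c
            table = ContingencyTable(a, b, c, d)
            results.append(
                EnrichmentResult(
                    experiment_id=str(experiment_id),
                    tf_name=str(tf_name),
                    table=table,
                    p_value=fisher_exact_one_tailed(table),
                    direction_label=label,
                )
            )
    q_values = benjamini_hochberg([r.p_value for r in results])
    results = [
        EnrichmentResult(
            r.experiment_id, r.tf_name, r.table, r.p_value, q, r.direction_label
        )
        for r, q in zip(results, q_values)
    ]

    net = TransOmicsNetwork(
        metadata={
            "network": "gene_regulatory",
            "fdr_threshold": cfg.fdr_threshold,
            "enrichment_mode": cfg.enrichment_mode.value,
            "condition": mrna.condition_label,
        }
    )
    directions = mrna.directions

    def _add_target(ident: str) -> Molecule:
        return net.add_molecule(
            Molecule(ident, Layer.MRNA, mrna.compartment, directions[ident])
        )

    for res in results:
        if res.q_value > cfg.fdr_threshold or res.table.a < 1:
            continue
        tf = net.add_molecule(Molecule(res.tf_name, Layer.TF))
        de = de_sets[res.direction_label]
        _, targets = experiment_targets[res.experiment_id]
        for ident in sorted(de & targets):
            target = _add_target(ident)
            net.add_edge(
                RegulationEdge(
                    tf.key,
                    target.key,
                    EdgeType.TF_TARGET,
                    evidence=f"experiment={res.experiment_id};q={res.q_value:.4g}",
                )
            )

    changed = mrna.ids
    for mirna_id, rows in kb.mirna_targets.groupby("mirna_id", sort=True):
        hit = set(rows["target_gene"]) & changed
        if not hit:
            continue
        mirna = net.add_molecule(Molecule(str(mirna_id), Layer.MIRNA))
        for ident in sorted(hit):
            target = _add_target(ident)
            net.add_edge(
                RegulationEdge(
                    mirna.key, target.key, EdgeType.MIRNA_TARGET, evidence="mirna_targets"
                )
            )
    return net, results


# ---------------------------------------------------------------------------
# B. PPI network
# ---------------------------------------------------------------------------

def build_ppi_network(
    mols: OmicsTable,
    kb: KnowledgeBase,
    cfg: BuildConfig = BuildConfig(),
) -> TransOmicsNetwork:
    """Unsigned PPI network restricted to uploaded molecules.

    Nodes are uploaded molecules appearing anywhere in the PPI table
    (isolated ones are kept); edges connect uploaded pairs whose combined
    score reaches ``cfg.ppi_score_threshold``.  With
    ``cfg.include_ppi_neighbors`` the first KB neighbours of uploaded
    molecules are pulled in as direction-unknown nodes.
    """
    if mols.layer not in (Layer.MRNA, Layer.PROTEIN):
        raise ValueError("PPI builder expects an mRNA or protein table")
    if not mols.records:
        raise ValueError("input table is empty")
    net = TransOmicsNetwork(
        metadata={
            "network": "ppi",
            "ppi_score_threshold": cfg.ppi_score_threshold,
            "condition": mols.condition_label,
        }
    )
    uploaded = mols.ids
    directions = mols.directions
    links = kb.ppi_links
    in_kb = set(links["protein_a"]) | set(links["protein_b"])
    for ident in sorted(uploaded & in_kb):
        net.add_molecule(Molecule(ident, mols.layer, mols.compartment, directions[ident]))
    for _, row in links.iterrows():
        if int(row["combined_score"]) < cfg.ppi_score_threshold:
            continue
        a, b, score = row["protein_a"], row["protein_b"], int(row["combined_score"])
        if a == b:
            continue
        a_up, b_up = a in uploaded, b in uploaded
        if a_up and b_up:
            pass
        elif cfg.include_ppi_neighbors and (a_up or b_up):
            other = b if a_up else a
            net.add_molecule(Molecule(other, mols.layer, mols.compartment))
        else:
            continue
        net.add_edge(
            RegulationEdge(
                (a, mols.layer, mols.compartment),
                (b, mols.layer, mols.compartment),
                EdgeType.PPI,
                evidence=f"combined_score={score}",
            )
        )
    return net


# ---------------------------------------------------------------------------
# C. metabolic network
# ---------------------------------------------------------------------------

def build_metabolic_network(
    mrna: OmicsTable,
    metab: OmicsTable,
    kb: KnowledgeBase,
    cfg: BuildConfig = BuildConfig(),
) -> TransOmicsNetwork:
    """Reaction-centred network of differential metabolic regulation.

    A reaction node exists iff at least one changed mRNA maps to one of its
    EC numbers or at least one changed tissue metabolite is a substrate,
    product or allosteric regulator of it.  Edges run molecule → reaction,
    typed by role and signed by :func:`classify_regulation_sign`.
    """
    if metab.compartment is not Compartment.TISSUE:
        raise ValueError("metabolic builder expects tissue-compartment metabolites")
    if not mrna.records and not metab.records:
        raise ValueError("both omics tables are empty")
    net = TransOmicsNetwork(
        metadata={"network": "metabolic", "condition": mrna.condition_label or metab.condition_label}
    )
    gene_dir = mrna.directions
    met_dir = metab.directions

    # reaction_id -> (pathway_id, ec set) and per-role changed hits
    reactions = kb.reactions
    ec_to_allosteric = {
        str(ec): rows for ec, rows in kb.allosteric.groupby("ec_number", sort=True)
    }
    for reaction_id, rows in reactions.groupby("reaction_id", sort=True):
        pathway = next((p for p in rows["pathway_id"] if p), None)
        hits: list[tuple[str, RegulatorRole, Direction, str]] = []
        ec_numbers = sorted({e for e in rows["ec_number"] if e})
        for _, row in rows.iterrows():
            if row["gene"] and row["gene"] in gene_dir:
                hits.append(
                    (row["gene"], RegulatorRole.ENZYME_MRNA, gene_dir[row["gene"]],
                     f"ec={row['ec_number']}")
                )
            if row["compound_id"] and row["compound_id"] in met_dir:
                role = (
                    RegulatorRole.SUBSTRATE
                    if row["role"] == "substrate"
                    else RegulatorRole.PRODUCT
                )
                hits.append(
                    (row["compound_id"], role, met_dir[row["compound_id"]], "kegg_reaction")
                )
        for ec in ec_numbers:
            allo = ec_to_allosteric.get(ec)
            if allo is None:
                continue
            for _, arow in allo.iterrows():
                cid = arow["compound_id"]
                if cid in met_dir:
                    role = (
                        RegulatorRole.ALLOSTERIC_ACTIVATOR
                        if arow["mode"] == "activator"
                        else RegulatorRole.ALLOSTERIC_INHIBITOR
                    )
                    flag = ";ambiguous" if bool(arow.get("ambiguous", False)) else ""
                    hits.append((cid, role, met_dir[cid], f"brenda;ec={ec}{flag}"))
        if not hits:
            continue
        reaction = net.add_molecule(
            Molecule(str(reaction_id), Layer.REACTION, pathway_id=pathway)
        )
        for ident, role, direction, evidence in hits:
            if role is RegulatorRole.ENZYME_MRNA:
                source = net.add_molecule(
                    Molecule(ident, Layer.MRNA, mrna.compartment, direction)
                )
            else:
                source = net.add_molecule(
                    Molecule(ident, Layer.METABOLITE, metab.compartment, direction)
                )
            net.add_edge(
                RegulationEdge(
                    source.key,
                    reaction.key,
                    _ROLE_EDGE_TYPE[role],
                    sign=classify_regulation_sign(role, direction),
                    evidence=evidence,
                )
            )
    return net


# ---------------------------------------------------------------------------
# D. metabolite exchange network
# ---------------------------------------------------------------------------

def build_exchange_network(
    mrna: OmicsTable,
    metab_tissue: OmicsTable,
    metab_blood: OmicsTable,
    kb: KnowledgeBase,
    cfg: BuildConfig = BuildConfig(),
) -> TransOmicsNetwork:
    """Transporter-centred network linking tissue and blood metabolite
    pools.

    A transporter node exists iff its gene is a changed mRNA or one of its
    substrate compounds changed in tissue or blood.  The same metabolite
    changed in both compartments yields two ``transport_substrate`` edges
    from two distinct (compartment-keyed) nodes.
    """
    if metab_tissue.compartment is not Compartment.TISSUE:
        raise ValueError("metab_tissue must carry compartment=tissue")
    if metab_blood.compartment is not Compartment.BLOOD:
        raise ValueError("metab_blood must carry compartment=blood")
    if not (mrna.records or metab_tissue.records or metab_blood.records):
        raise ValueError("all three omics tables are empty")
    net = TransOmicsNetwork(
        metadata={"network": "exchange", "condition": mrna.condition_label}
    )
    gene_dir = mrna.directions
    tissue_dir = metab_tissue.directions
    blood_dir = metab_blood.directions

    for transporter_id, rows in kb.transporters.groupby("transporter_id", sort=True):
        hits: list[tuple[Molecule, RegulatorRole, Direction, str]] = []
        for gene in sorted({g for g in rows["gene"] if g}):
            if gene in gene_dir:
                hits.append(
                    (
                        Molecule(gene, Layer.MRNA, mrna.compartment, gene_dir[gene]),
                        RegulatorRole.TRANSPORTER_MRNA,
                        gene_dir[gene],
                        "tcdb_gene",
                    )
                )
        for cid in sorted({c for c in rows["compound_id"] if c}):
            if cid in tissue_dir:
                hits.append(
                    (
                        Molecule(cid, Layer.METABOLITE, Compartment.TISSUE, tissue_dir[cid]),
                        RegulatorRole.TRANSPORT_SUBSTRATE,
                        tissue_dir[cid],
                        "tcdb_substrate;compartment=tissue",
                    )
                )
            if cid in blood_dir:
                hits.append(
                    (
                        Molecule(cid, Layer.METABOLITE, Compartment.BLOOD, blood_dir[cid]),
                        RegulatorRole.TRANSPORT_SUBSTRATE,
                        blood_dir[cid],
                        "tcdb_substrate;compartment=blood",
                    )
                )
        if not hits:
            continue
        transporter = net.add_molecule(Molecule(str(transporter_id), Layer.TRANSPORTER))
        for mol, role, direction, evidence in hits:
            source = net.add_molecule(mol)
            net.add_edge(
                RegulationEdge(
                    source.key,
                    transporter.key,
                    _ROLE_EDGE_TYPE[role],
                    sign=classify_regulation_sign(role, direction),
                    evidence=evidence,
                )
            )
    return net


# ---------------------------------------------------------------------------
# regulation-source classification (reaction/transporter Venn counts)
# ---------------------------------------------------------------------------

_MRNA_EDGE_TYPES = {EdgeType.ENZYME_MRNA, EdgeType.TRANSPORTER_MRNA}
_METABOLITE_EDGE_TYPES = {
    EdgeType.SUBSTRATE,
    EdgeType.PRODUCT,
    EdgeType.ALLOSTERIC_ACTIVATION,
    EdgeType.ALLOSTERIC_INHIBITION,
    EdgeType.TRANSPORT_SUBSTRATE,
}


@dataclass
class RegulationSourceSummary:
    """Counts of reactions/transporters regulated by mRNAs only,
    metabolites only, or both."""

    flags: dict = field(default_factory=dict)  # node key -> (by_mrna, by_metabolite)
    n_mrna_only: int = 0
    n_metabolite_only: int = 0
    n_both: int = 0

    @property
    def n_regulated(self) -> int:
        return self.n_mrna_only + self.n_metabolite_only + self.n_both


def classify_regulation_source(net: TransOmicsNetwork) -> RegulationSourceSummary:
    """Classify each reaction/transporter node by whether its incident
    regulation comes from mRNAs, metabolites, or both."""
    summary = RegulationSourceSummary()
    centers = [m for m in net.nodes if m.layer in (Layer.REACTION, Layer.TRANSPORTER)]
    if not centers:
        raise ValueError("network contains no reaction or transporter nodes")
    for mol in centers:
        by_mrna = by_met = False
        for edge in net.edges_incident(mol.key):
            if edge.edge_type in _MRNA_EDGE_TYPES:
                by_mrna = True
            elif edge.edge_type in _METABOLITE_EDGE_TYPES:
                by_met = True
        summary.flags[mol.key] = (by_mrna, by_met)
        if by_mrna and by_met:
            summary.n_both += 1
        elif by_mrna:
            summary.n_mrna_only += 1
        elif by_met:
            summary.n_metabolite_only += 1
    return summary
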