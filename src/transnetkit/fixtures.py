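"""Synthetic fixture generation: toy knowledge bases, omics inputs with a
planted enriched TF, and networks with a planted degree-distribution
scaling exponent.

These generators are the offline test substrate for the whole package.
They emulate the *structure* of the real inputs — knowledge-base tables in
the six supported dialects, two-column omics tables, majority-leaves
minority-hubs topologies — not the biology of any particular dataset.  All
randomness flows through one seeded ``numpy`` generator, so identical
specs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .graph_core import (
    Compartment,
    EdgeType,
    Layer,
    Molecule,
    RegulationEdge,
    TransOmicsNetwork,
)
from .kb_readers import KnowledgeBase, empty_table, load_mirna_targets, load_tf_targets

__all__ = [
    "FixtureSpec",
    "PlantedEnrichment",
    "PlantedGamma",
    "generate_toy_kb",
    "generate_omics_with_planted_enrichment",
    "load_planted_enrichment_kb",
    "generate_mlmh_network",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PlantedEnrichment:
    """A TF whose target set overlaps the changed-gene list by construction.

    The defaults plant a strong, unambiguous signal: 10 of 12 changed genes
    among 20 targets drawn from a background of 100."""

    tf: str = "TF_PLANTED"
    n_targets: int = 20
    n_de: int = 12
    n_de_overlap: int = 10
    background_size: int = 100
    n_decoys: int = 8

    def __post_init__(self) -> None:
        if self.n_de_overlap > self.n_targets or self.n_de_overlap > self.n_de:
            raise ValueError("n_de_overlap cannot exceed n_targets or n_de")
        if self.n_targets > self.background_size or self.n_de > self.background_size:
            raise ValueError("target and DE sets must fit in the background")
        if self.n_de - self.n_de_overlap > self.background_size - self.n_targets:
            raise ValueError("infeasible overlap: too few non-target genes")


@dataclass(frozen=True)
class PlantedGamma:
    """Spec of a majority-leaves minority-hubs network with expected degree
    counts E[N_k] = C k^-gamma on k = 1..k_max.

    ``mode="sampled"`` (default) draws each node's degree i.i.d. from
    P(k) ∝ k^-gamma, so seeded replicates carry genuine sampling noise and
    confidence-interval calibration is meaningful.  ``mode="expected"``
    uses the deterministic rounded histogram N_k = round(C k^-gamma),
    which is identical for every seed.  ``k_max=None`` uses the natural
    cutoff where the expected count falls below 1, avoiding a
    rounded-to-zero tail plateau."""

    gamma: float = 2.0
    n_nodes: int = 2000
    k_max: Optional[int] = None
    mode: str = "sampled"

    def __post_init__(self) -> None:
        if not (1 < self.gamma <= 4):
            raise ValueError("planted gamma must lie in (1, 4]")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be at least 10")
        if self.mode not in ("sampled", "expected"):
            raise ValueError("mode must be 'sampled' or 'expected'")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_genes: int = 40
    n_metabolites: int = 18
    n_reactions: int = 8
    n_tfs: int = 4
    n_mirnas: int = 3
    n_transporters: int = 5
    planted_tf: Optional[PlantedEnrichment] = None
    planted_gamma: Optional[PlantedGamma] = None

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_metabolites", "n_reactions", "n_tfs", "n_mirnas", "n_transporters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _compound_ids(n: int) -> list[str]:
    return [f"C{i:05d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# toy knowledge base
# ---------------------------------------------------------------------------

def generate_toy_kb(spec: FixtureSpec, outdir: PathLike) -> dict[str, Path]:
    """Write an internally consistent six-table toy knowledge base.

    Every reaction gets at least one substrate, one product and one gene;
    transporter-substrate ChEBI degrees straddle the 50 cutoff; PPI scores
    straddle 400; one allosteric compound name is deliberately
    unresolvable.  Deterministic given ``spec.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    compounds = _compound_ids(spec.n_metabolites)
    paths: dict[str, Path] = {}

    # --- tf_targets: one ChIP experiment per TF -----------------------
    rows = []
    for i in range(spec.n_tfs):
        tf = f"TF{i + 1:02d}"
        n_tgt = int(rng.integers(5, max(6, spec.n_genes // 2)))
        targets = rng.choice(genes, size=n_tgt, replace=False)
        for g in sorted(targets):
            rows.append(
                {
                    "experiment_id": f"EXP{i + 1:03d}",
                    "tf_name": tf,
                    "target_gene": g,
                    "binding_score": int(rng.integers(10, 300)),
                    "tss_window_kb": 1,
                }
            )
    paths["tf_targets"] = outdir / "tf_targets.tsv"
    pd.DataFrame(rows).to_csv(paths["tf_targets"], sep="\t", index=False)

    # --- mirna_targets ------------------------------------------------
    rows = []
    for i in range(spec.n_mirnas):
        mirna = f"mmu-miR-{100 + i}"
        targets = rng.choice(genes, size=int(rng.integers(2, 6)), replace=False)
        for g in sorted(targets):
            rows.append({"mirna_id": mirna, "target_gene": g, "support_type": "functional"})
    paths["mirna_targets"] = outdir / "mirna_targets.tsv"
    pd.DataFrame(rows).to_csv(paths["mirna_targets"], sep="\t", index=False)

    # --- ppi_links: scores straddling the 400 default -----------------
    rows = []
    n_links = max(6, spec.n_genes)
    seen_pairs = set()
    fixed_scores = [399, 400, 401]
    while len(rows) < n_links:
        a, b = rng.choice(genes, size=2, replace=False)
        pair = tuple(sorted((a, b)))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        score = (
            fixed_scores[len(rows)]
            if len(rows) < len(fixed_scores)
            else int(rng.integers(150, 1000))
        )
        rows.append({"protein_a": pair[0], "protein_b": pair[1], "combined_score": score})
    paths["ppi_links"] = outdir / "ppi_links.tsv"
    pd.DataFrame(rows).to_csv(paths["ppi_links"], sep="\t", index=False)

    # --- reactions ----------------------------------------------------
    rows = []
    for i in range(spec.n_reactions):
        rid = f"R{i + 1:03d}"
        ec = f"{int(rng.integers(1, 7))}.{int(rng.integers(1, 10))}.{int(rng.integers(1, 10))}.{i + 1}"
        pathway = f"path{1 + i % 3:05d}"
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        pool = rng.choice(compounds, size=n_sub + n_prod, replace=False)
        for c in sorted(pool[:n_sub]):
            rows.append(
                {"reaction_id": rid, "ec_number": ec, "gene": "", "compound_id": c,
                 "role": "substrate", "pathway_id": pathway}
            )
        for c in sorted(pool[n_sub:]):
            rows.append(
                {"reaction_id": rid, "ec_number": ec, "gene": "", "compound_id": c,
                 "role": "product", "pathway_id": pathway}
            )
        for g in sorted(rng.choice(genes, size=int(rng.integers(1, 3)), replace=False)):
            rows.append(
                {"reaction_id": rid, "ec_number": ec, "gene": g, "compound_id": "",
                 "role": "", "pathway_id": pathway}
            )
    reactions_df = pd.DataFrame(rows)
    paths["reactions"] = outdir / "reactions.tsv"
    reactions_df.to_csv(paths["reactions"], sep="\t", index=False)

    # --- allosteric + name map ---------------------------------------
    ecs = sorted(set(reactions_df["ec_number"]))
    name_rows = []
    for j, cid in enumerate(compounds):
        name_rows.append(
            {
                "compound_id": cid,
                "inchikey": f"IK{j + 1:04d}AAAAAAAAAA",
                "name": f"compound {j + 1}",
                "synonyms": f"cpd-{j + 1}|metab_{j + 1}",
            }
        )
    name_map = pd.DataFrame(name_rows)
    paths["name_map"] = outdir / "name_map.tsv"
    name_map.to_csv(paths["name_map"], sep="\t", index=False)

    rows = []
    for ec in ecs:
        for _ in range(int(rng.integers(1, 3))):
            j = int(rng.integers(0, len(compounds)))
            mode = "activator" if rng.random() < 0.5 else "inhibitor"
            style = rng.random()
            if style < 0.4:
                rows.append({"ec_number": ec, "compound_name": f"compound {j + 1}",
                             "inchikey": "", "mode": mode})
            elif style < 0.7:
                rows.append({"ec_number": ec, "compound_name": f"arbitrary name {j}",
                             "inchikey": f"IK{j + 1:04d}AAAAAAAAAA", "mode": mode})
            else:
                rows.append({"ec_number": ec, "compound_name": f"cpd-{j + 1}",
                             "inchikey": "", "mode": mode})
    rows.append({"ec_number": ecs[0], "compound_name": "unmappable-xyz", "inchikey": "",
                 "mode": "inhibitor"})
    paths["allosteric"] = outdir / "allosteric.tsv"
    pd.DataFrame(rows).to_csv(paths["allosteric"], sep="\t", index=False)

    # --- transporters: degrees straddling 50, membrane flags mixed ----
    rows = []
    fixed_degrees = [49, 50, 5]
    for i in range(spec.n_transporters):
        tid = f"TC{i + 1:03d}"
        gene = genes[int(rng.integers(0, len(genes)))]
        n_cpd = int(rng.integers(1, 4))
        cpds = rng.choice(compounds, size=n_cpd, replace=False)
        for k, c in enumerate(sorted(cpds)):
            deg = (
                fixed_degrees[(i + k) % len(fixed_degrees)]
                if i < 2
                else int(rng.integers(1, 80))
            )
            membrane = "true" if (i != spec.n_transporters - 1) else "false"
            rows.append(
                {"transporter_id": tid, "gene": gene, "compound_id": c,
                 "chebi_degree": deg, "membrane_localized": membrane}
            )
    paths["transporters"] = outdir / "transporters.tsv"
    pd.DataFrame(rows).to_csv(paths["transporters"], sep="\t", index=False)

    meta = {"seed": spec.seed, "n_genes": spec.n_genes, "n_metabolites": spec.n_metabolites,
            "n_reactions": spec.n_reactions, "n_tfs": spec.n_tfs,
            "n_transporters": spec.n_transporters}
    (outdir / "fixture_meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# planted enrichment
# ---------------------------------------------------------------------------

def generate_omics_with_planted_enrichment(
    spec: FixtureSpec, outdir: PathLike
) -> dict:
    """Write an mRNA omics table, background list and ChIP target-gene
    table in which exactly one experiment (the planted TF) is enriched.

    The changed-gene list overlaps the planted TF's targets in exactly
    ``n_de_overlap`` genes.  Decoy experiments are built with their overlap
    pinned to the rounded chance expectation, so the planted TF is the
    unique enriched experiment for any seed.  Returns the ground-truth
    record (also written to ``ground_truth.yaml``).
    """
    if spec.planted_tf is None:
        raise ValueError("spec.planted_tf must be set")
    p = spec.planted_tf
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    background = [f"BG{i:05d}" for i in range(1, p.background_size + 1)]
    shuffled = [str(g) for g in rng.permutation(background)]
    targets = sorted(shuffled[: p.n_targets])
    non_targets = shuffled[p.n_targets :]
    de = sorted(targets[: p.n_de_overlap] + non_targets[: p.n_de - p.n_de_overlap])
    # order within targets is already random via the permutation
    de_set = set(de)

    rows = []
    for g in targets:
        rows.append({"experiment_id": "EXP_PLANTED", "tf_name": p.tf, "target_gene": g,
                     "binding_score": 100, "tss_window_kb": 1})
    chance_overlap = round(p.n_de * p.n_targets / p.background_size)
    de_list = sorted(de_set)
    non_de = [g for g in background if g not in de_set]
    for d in range(p.n_decoys):
        # deterministic chance-level overlap, random gene identities
        pick_de = [str(g) for g in rng.permutation(de_list)][:chance_overlap]
        pick_non = [str(g) for g in rng.permutation(non_de)][: p.n_targets - chance_overlap]
        for g in sorted(pick_de + pick_non):
            rows.append({"experiment_id": f"EXP_DECOY{d + 1:02d}", "tf_name": f"TF_DECOY{d + 1:02d}",
                         "target_gene": g, "binding_score": 100, "tss_window_kb": 1})
    tf_path = outdir / "tf_targets.tsv"
    pd.DataFrame(rows).to_csv(tf_path, sep="\t", index=False)

    mirna_path = outdir / "mirna_targets.tsv"
    pd.DataFrame(columns=["mirna_id", "target_gene", "support_type"]).to_csv(
        mirna_path, sep="\t", index=False
    )

    omics_path = outdir / "mrna_omics.tsv"
    pd.DataFrame({"id": de, "response": ["increased"] * len(de)}).to_csv(
        omics_path, sep="\t", index=False
    )
    background_path = outdir / "background_genes.txt"
    background_path.write_text("\n".join(background) + "\n")

    a = p.n_de_overlap
    b = p.n_de - a
    c = p.n_targets - a
    d = p.background_size - a - b - c
    truth = {
        "seed": spec.seed,
        "tf": p.tf,
        "experiment_id": "EXP_PLANTED",
        "contingency": {"a": a, "b": b, "c": c, "d": d},
        "de_genes": de,
        "targets": targets,
        "expected_edges": sorted(set(targets) & de_set),
        "files": {
            "tf_targets": str(tf_path),
            "mirna_targets": str(mirna_path),
            "omics": str(omics_path),
            "background": str(background_path),
        },
    }
    (outdir / "ground_truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    return truth


def load_planted_enrichment_kb(outdir: PathLike) -> KnowledgeBase:
    """Load the planted-enrichment fixture directory as a KnowledgeBase
    (the four unrelated tables are empty)."""
    outdir = Path(outdir)
    return KnowledgeBase(
        tf_targets=load_tf_targets(outdir / "tf_targets.tsv", 1, 0),
        mirna_targets=load_mirna_targets(outdir / "mirna_targets.tsv"),
        ppi_links=empty_table("ppi_links"),
        reactions=empty_table("reactions"),
        allosteric=empty_table("allosteric"),
        transporters=empty_table("transporters"),
    )


# ---------------------------------------------------------------------------
# planted-gamma network (configuration model)
# ---------------------------------------------------------------------------

def _support(pg: PlantedGamma) -> np.ndarray:
    """Degree support k = 1..k_max (natural cutoff at expected count 1
    when k_max is unset)."""
    if pg.k_max is not None:
        return np.arange(1, pg.k_max + 1)
    k_cap = max(3, int(pg.n_nodes ** (1.0 / pg.gamma)) * 2)
    ks = np.arange(1, k_cap + 1)
    c = pg.n_nodes / np.sum(ks ** (-pg.gamma))
    return ks[c * ks.astype(float) ** (-pg.gamma) >= 1.0]


def planted_degree_histogram(pg: PlantedGamma) -> list[tuple[int, int]]:
    """Deterministic expected histogram N_k = round(C k^-gamma), with C
    scaled so that the node total is ~``n_nodes``."""
    ks = _support(pg)
    c = pg.n_nodes / np.sum(ks ** (-pg.gamma))
    counts = np.round(c * ks.astype(float) ** (-pg.gamma)).astype(int)
    return [(int(k), int(nk)) for k, nk in zip(ks, counts) if nk > 0]


def _draw_degree_sequence(pg: PlantedGamma, rng: np.random.Generator) -> list[int]:
    if pg.mode == "expected":
        return [k for k, nk in planted_degree_histogram(pg) for _ in range(nk)]
    ks = _support(pg)
    pmf = ks.astype(float) ** (-pg.gamma)
    pmf /= pmf.sum()
    return [int(k) for k in rng.choice(ks, size=pg.n_nodes, p=pmf)]


def generate_mlmh_network(spec: FixtureSpec) -> TransOmicsNetwork:
    """Realize a majority-leaves minority-hubs network with a planted
    scaling exponent by configuration-model stub matching.

    Self-loops and parallel edges are repaired by random pair swaps that
    preserve the degree sequence; in the rare case a conflict cannot be
    repaired the offending stub pair is dropped (recorded in metadata).
    An odd stub total is fixed by appending one degree-1 node.
    """
    if spec.planted_gamma is None:
        raise ValueError("spec.planted_gamma must be set")
    pg = spec.planted_gamma
    rng = np.random.default_rng(spec.seed)
    degrees = _draw_degree_sequence(pg, rng)
    if sum(degrees) % 2 == 1:
        degrees.append(1)  # documented parity fix

    stubs = np.repeat(np.arange(len(degrees)), degrees)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)

    edge_set: set[tuple[int, int]] = set()
    good: list[tuple[int, int]] = []
    bad: list[tuple[int, int]] = []
    for u, v in pairs:
        u, v = int(u), int(v)
        e = (min(u, v), max(u, v))
        if u == v or e in edge_set:
            bad.append((u, v))
        else:
            edge_set.add(e)
            good.append((u, v))

    dropped = 0
    max_tries = 200
    for u, v in bad:
        fixed = False
        for _ in range(max_tries):
            j = int(rng.integers(0, len(good)))
            a, b = good[j]
            # swap second endpoints: (u, b), (a, v)
            e1 = (min(u, b), max(u, b))
            e2 = (min(a, v), max(a, v))
            old = (min(a, b), max(a, b))
            if u == b or a == v or e1 == e2 or e1 in edge_set or e2 in edge_set:
                continue
            edge_set.discard(old)
            edge_set.add(e1)
            edge_set.add(e2)
            good[j] = (u, b)
            good.append((a, v))
            fixed = True
            break
        if not fixed:
            dropped += 1

    net = TransOmicsNetwork(
        metadata={
            "network": "mlmh_fixture",
            "planted_gamma": pg.gamma,
            "seed": spec.seed,
            "dropped_stub_pairs": dropped,
        }
    )
    width = len(str(len(degrees)))
    names = [f"N{i + 1:0{width}d}" for i in range(len(degrees))]
    for name in names:
        net.add_molecule(Molecule(name, Layer.MRNA))
    for u, v in sorted(edge_set):
        net.add_edge(
            RegulationEdge(
                (names[u], Layer.MRNA, Compartment.NONE),
                (names[v], Layer.MRNA, Compartment.NONE),
                EdgeType.PPI,
                evidence="mlmh_fixture",
            )
        )
    return net
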