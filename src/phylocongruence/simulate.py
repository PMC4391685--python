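"""Synthetic co-evolution / horizontal-transfer data generator.

Emulates the statistical structure the congruence analysis assumes: one
ultrametric species tree (Yule) shared by all loci; a 16S-like nucleotide
marker evolved on it under JC69; protein-coding resistance genes evolved
under JTT on gene trees decoupled from the species tree by a tunable
number of subtree-prune-and-regraft (SPR) transfers; five housekeeping
proteins evolved on the species tree for the multi-locus concatenation;
joint gene presence/absence with a tunable co-occurrence odds ratio;
pH-like and organic-matter-like site covariates with Brownian-motion
phylogenetic signal; and homology-hit plus gene-neighborhood tables (with
decoys) exercising the curation rules.  A ledger of realized truths
accompanies every dataset so downstream expectations are verifiable.

Default parameters mirror the isolate survey the generator stands in
for: 90 strains, a 750-nt partial 16S marker, 250-aa partial proteins,
marginal gene frequencies 7/90 and 18/90, and a streptomycete-like
subgroup fraction of 79/90.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .distances import AMINO_ACIDS, NUCLEOTIDES, jtt_model
from .errors import SimulationError
from .io_formats import (
    DNA,
    PROTEIN,
    Alignment,
    write_alignment,
    write_newick,
    write_table,
)
from .mls import DEFAULT_GENES

_SEED_CAP = 2**31 - 1


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    hgt_events may be a single integer (applied to every resistance gene)
    or a mapping gene-name -> SPR count; the default decouples the ABC
    transporter gene while the erm gene stays vertically inherited.
    """

    n_taxa: int = 90
    tree_model: str = "yule"
    birth_rate: float = 1.0
    seq_length_nt: int = 750
    seq_length_aa: int = 250
    hgt_events: object = field(default_factory=lambda: {"erm": 0, "abc": 3})
    marker_rate: float = 0.02
    protein_rate: float = 0.15
    presence_prob: tuple = (7 / 90, 18 / 90)
    co_occurrence_logodds: float = 2.0
    env_bm_sigma: float = 1.0
    env_noise_sd: float = 0.3
    subgroup_fraction: float = 79 / 90
    phenotype_base_prob: float = 13 / 90
    phenotype_logodds: float = -1.5
    decoy_subthreshold: int = 3
    decoy_ksga: int = 3
    n_missing_housekeeping: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise SimulationError("n_taxa must be >= 4")
        if self.seq_length_nt < 1 or self.seq_length_aa < 1:
            raise SimulationError("sequence lengths must be >= 1")
        if self.tree_model != "yule":
            raise SimulationError("only the Yule tree model is supported")
        if self.birth_rate <= 0:
            raise SimulationError("birth_rate must be positive")

    def hgt_for(self, gene: str) -> int:
        if isinstance(self.hgt_events, dict):
            return int(self.hgt_events.get(gene, 0))
        return int(self.hgt_events)


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, plus the truth ledger."""

    config: SimulationConfig
    species_tree: dendropy.Tree
    gene_trees: dict
    marker_alignment: Alignment
    gene_alignments: dict
    housekeeping_alignments: dict
    presence: pd.DataFrame
    phenotype: pd.DataFrame
    site_metadata: pd.DataFrame
    erm_hits: pd.DataFrame
    abc_hits: pd.DataFrame
    neighborhoods: pd.DataFrame
    subgroup: list
    ledger: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_newick(self.species_tree, out / "species_tree.nwk")
        for gene, tree in self.gene_trees.items():
            write_newick(tree, out / f"gene_tree_{gene}.nwk")
        write_alignment(self.marker_alignment, out / "marker_16S.fasta")
        for gene, aln in self.gene_alignments.items():
            write_alignment(aln, out / f"gene_{gene}.faa")
        for gene, aln in self.housekeeping_alignments.items():
            write_alignment(aln, out / f"housekeeping_{gene}.faa")
        write_table(self.presence, out / "presence.tsv")
        write_table(self.phenotype, out / "phenotype.tsv")
        write_table(self.site_metadata, out / "site_metadata.tsv")
        write_table(self.erm_hits, out / "hits_erm.tsv")
        write_table(self.abc_hits, out / "hits_abc.tsv")
        write_table(self.neighborhoods, out / "neighborhoods.tsv")
        (out / "subgroup.txt").write_text("\n".join(self.subgroup) + "\n")
        cfg = asdict(self.config)
        ledger = dict(self.ledger, config=cfg)
        (out / "ledger.json").write_text(json.dumps(ledger, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# species tree


def _taxon_labels(n: int) -> list:
    width = max(3, len(str(n)))
    return [f"t{i + 1:0{width}d}" for i in range(n)]


def simulate_species_tree(cfg: SimulationConfig, seed=None) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree with ``cfg.n_taxa`` leaves.

    With k extant lineages the waiting time to the next split is
    Exponential(k * birth_rate); a uniformly chosen lineage splits.  The
    expected root height is sum_{k=2..n} 1/(k * birth_rate).  Node ages
    are stored on each node as ``.age`` (leaves at 0).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, lam = cfg.n_taxa, cfg.birth_rate
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    root.split_time = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
    t = 0.0
    for k in range(2, n):
        t += rng.exponential(1.0 / (k * lam))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / (n * lam))
    height = t
    # assign labels to leaves in random order: strain identity must carry no
    # information about tree position, or permutation nulls break
    leaves = [nd for nd in _preorder(root) if not nd.child_nodes()]
    labels = _taxon_labels(n)
    rng.shuffle(labels)
    for label, leaf in zip(labels, leaves):
        taxon = tns.new_taxon(label)
        leaf.taxon = taxon
    for nd in _preorder(root):
        nd.age = 0.0 if not nd.child_nodes() else height - nd.split_time
    _lengths_from_ages(root)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


def _preorder(node):
    stack = [node]
    while stack:
        nd = stack.pop()
        yield nd
        stack.extend(reversed(nd.child_nodes()))


def _lengths_from_ages(root) -> None:
    for nd in _preorder(root):
        for child in nd.child_nodes():
            child.edge.length = nd.age - child.age


def _set_ages_from_lengths(tree) -> None:
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd.age = 0.0
        else:
            child = nd.child_nodes()[0]
            nd.age = child.age + child.edge.length


def tree_height(tree: dendropy.Tree) -> float:
    _set_ages_from_lengths(tree)
    return tree.seed_node.age


# ---------------------------------------------------------------------------
# horizontal transfer


def _is_within(node, ancestor) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent_node
    return False


def apply_hgt(species_tree: dendropy.Tree, hgt_events: int, seed: int) -> dendropy.Tree:
    """Decouple a gene tree from the species tree by random SPR transfers.

    Each event prunes a uniformly chosen non-root subtree and regrafts it
    onto a uniformly chosen valid recipient edge (outside the pruned
    subtree, excluding its own parent and sister edges, and old enough to
    accommodate the subtree); the attachment age is uniform on the
    feasible span of the recipient edge, so the gene tree stays
    ultrametric.
    """
    if len(species_tree.taxon_namespace) < 4:
        raise SimulationError("HGT simulation needs at least 4 taxa")
    tree = species_tree.clone(depth=1)
    _set_ages_from_lengths(tree)
    rng = np.random.default_rng(seed)
    for _ in range(int(hgt_events)):
        _spr_once(tree, rng)
    _lengths_from_ages(tree.seed_node)
    return tree


def _spr_once(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    root = tree.seed_node
    nodes = [nd for nd in tree.preorder_node_iter() if nd is not root]
    candidates = []
    for u in nodes:
        parent = u.parent_node
        sibs = [c for c in parent.child_nodes() if c is not u]
        if len(sibs) != 1:
            continue
        sib = sibs[0]
        for c in nodes:
            if c is u or c is sib or c is parent:
                continue
            if _is_within(c, u):
                continue
            hi = c.parent_node.age
            lo = max(u.age, c.age)
            if hi > lo + 1e-12:
                candidates.append((u, c))
    if not candidates:
        raise SimulationError("no valid SPR donor/recipient pair")
    u, c = candidates[int(rng.integers(len(candidates)))]
    parent = u.parent_node
    sib = [x for x in parent.child_nodes() if x is not u][0]
    grand = parent.parent_node
    parent.remove_child(u)
    parent.remove_child(sib)
    if grand is None:
        tree.seed_node = sib
        sib.parent_node = None
    else:
        grand.remove_child(parent)
        grand.add_child(sib)
    q = c.parent_node
    lo = max(u.age, c.age)
    hi = q.age
    t_attach = float(rng.uniform(lo, hi))
    mid = dendropy.Node()
    mid.age = t_attach
    q.remove_child(c)
    q.add_child(mid)
    mid.add_child(c)
    mid.add_child(u)


# ---------------------------------------------------------------------------
# sequence evolution


def _jc69_probs(d: float) -> np.ndarray:
    same = 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)
    diff = 0.25 - 0.25 * math.exp(-4.0 * d / 3.0)
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def _sample_markov(parent_states, P, rng):
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.shape[0])
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def evolve_alignment(
    tree: dendropy.Tree, model: str, length: int, seed: int, rate: float = 1.0
) -> Alignment:
    """Evolve a gapless alignment along a tree under JC69 or JTT.

    The root sequence is drawn from the stationary frequencies; each
    branch applies the transition matrix P(rate * d) site-wise, where d
    is the branch length in tree-time units and ``rate`` is the locus
    clock rate (expected substitutions per site per unit tree time).
    """
    rng = np.random.default_rng(seed)
    if model == "JC69":
        pi = np.full(4, 0.25)
        trans = _jc69_probs
        states, alphabet = NUCLEOTIDES, DNA
    elif model == "JTT":
        sm = jtt_model()
        pi = sm.pi
        trans = sm.transition_probs
        states, alphabet = AMINO_ACIDS, PROTEIN
    else:
        raise SimulationError(f"unknown evolution model {model!r}")
    seqs = {}
    root = tree.seed_node
    root_states = rng.choice(len(states), size=length, p=pi)
    seqs[id(root)] = root_states
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        P = trans(rate * float(nd.edge.length or 0.0))
        seqs[id(nd)] = _sample_markov(seqs[id(nd.parent_node)], P, rng)
    labels, rows = [], []
    arr = np.array(list(states))
    for leaf in tree.leaf_node_iter():
        labels.append(leaf.taxon.label)
        rows.append("".join(arr[seqs[id(leaf)]]))
    return Alignment(tuple(labels), tuple(rows), alphabet)


# ---------------------------------------------------------------------------
# environment covariates


def _brownian(tree: dendropy.Tree, sigma: float, rng) -> dict:
    vals = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        bl = float(nd.edge.length or 0.0)
        vals[id(nd)] = vals[id(nd.parent_node)] + rng.normal(0.0, sigma * math.sqrt(bl))
    return vals


def simulate_environment(tree: dendropy.Tree, cfg: SimulationConfig, seed=None) -> pd.DataFrame:
    """Site covariates with Brownian phylogenetic signal along the tree.

    Two traits evolve by Brownian motion (scale ``env_bm_sigma``) with
    independent Gaussian noise ``env_noise_sd`` added per strain, then
    mapped onto soil-like scales: pH centered at 6.2 (unit spread) and
    organic-matter percent centered at 12 with a 5x spread.
    """
    rng = np.random.default_rng(cfg.seed + 7 if seed is None else seed)
    bm1 = _brownian(tree, cfg.env_bm_sigma, rng)
    bm2 = _brownian(tree, cfg.env_bm_sigma, rng)
    rows = []
    for i, leaf in enumerate(tree.leaf_node_iter()):
        x1 = bm1[id(leaf)] + rng.normal(0.0, cfg.env_noise_sd)
        x2 = bm2[id(leaf)] + rng.normal(0.0, cfg.env_noise_sd)
        rows.append(
            {
                "strain": leaf.taxon.label,
                "site": f"site_{i + 1:03d}",
                "pH": round(6.2 + x1, 3),
                "organic_matter": round(12.0 + 5.0 * x2, 3),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presence/absence and phenotype


def _joint_bernoulli_probs(p1: float, p2: float, logodds: float) -> np.ndarray:
    """Cell probabilities (p11, p10, p01, p00) with given margins and log-OR."""
    lo_feasible = max(0.0, p1 + p2 - 1.0)
    hi_feasible = min(p1, p2)
    if math.isinf(logodds) and logodds > 0:
        p11 = hi_feasible
    elif math.isinf(logodds):
        p11 = lo_feasible
    elif abs(logodds) < 1e-12:
        p11 = p1 * p2
    else:
        w = math.exp(logodds)
        s = 1.0 + (p1 + p2) * (w - 1.0)
        disc = s * s - 4.0 * w * (w - 1.0) * p1 * p2
        if disc < 0:
            raise SimulationError("infeasible (marginals, log-odds) combination")
        p11 = (s - math.sqrt(disc)) / (2.0 * (w - 1.0))
    p11 = min(max(p11, lo_feasible), hi_feasible)
    probs = np.array([p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11])
    if np.any(probs < -1e-9):
        raise SimulationError("infeasible (marginals, log-odds) combination")
    return np.clip(probs, 0.0, 1.0)


def simulate_presence(cfg: SimulationConfig, labels=None, seed=None):
    """Joint Bernoulli presence of the two resistance genes per strain.

    Returns (presence table, realized 2x2 counts [[a,b],[c,d]] with a =
    both genes present).
    """
    rng = np.random.default_rng(cfg.seed + 11 if seed is None else seed)
    labels = list(labels) if labels is not None else _taxon_labels(cfg.n_taxa)
    probs = _joint_bernoulli_probs(*cfg.presence_prob, cfg.co_occurrence_logodds)
    cats = rng.choice(4, size=len(labels), p=probs / probs.sum())
    erm = np.isin(cats, (0, 1)).astype(int)
    abc = np.isin(cats, (0, 2)).astype(int)
    df = pd.DataFrame({"strain": labels, "erm": erm, "abc": abc})
    table = [
        [int(np.sum((erm == 1) & (abc == 1))), int(np.sum((erm == 1) & (abc == 0)))],
        [int(np.sum((erm == 0) & (abc == 1))), int(np.sum((erm == 0) & (abc == 0)))],
    ]
    return df, table


def simulate_phenotype(cfg: SimulationConfig, presence: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Antibiotic-activity phenotype negatively coupled to ABC presence."""
    rng = np.random.default_rng(cfg.seed + 13 if seed is None else seed)
    base = math.log(cfg.phenotype_base_prob / (1.0 - cfg.phenotype_base_prob))
    logit = base + cfg.phenotype_logodds * presence["abc"].to_numpy()
    p = 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame(
        {
            "strain": presence["strain"],
            "active_ecoli": (rng.random(len(p)) < p).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# hit and neighborhood tables

_NEUTRAL_PRODUCTS = (
    "hypothetical protein",
    "MFS transporter",
    "transcriptional regulator, TetR family",
    "serine/threonine protein kinase",
    "ABC transporter permease",
    "acyl-CoA dehydrogenase",
    "two-component sensor histidine kinase",
)

_KSGA_NEIGHBOR_PRODUCTS = (
    "4-diphosphocytidyl-2-C-methyl-D-erythritol kinase IspE",
    "putative deoxyribonuclease, TatD family hydrolase",
    "methionyl-tRNA synthetase",
)


def emit_hit_tables(cfg: SimulationConfig, presence: pd.DataFrame, seed=None):
    """Homology-hit and neighborhood tables with ledgered expected outcomes.

    Every erm-positive genome receives one qualifying Erm hit in a
    neutral neighborhood; every abc-positive genome one qualifying ABC
    hit plus a weaker qualifying second hit and a sub-threshold hit (so
    best-per-genome selection is exercised).  Decoy genomes receive
    sub-threshold Erm hits or above-threshold hits sitting in a ksgA
    marker neighborhood.  Returns (erm_hits, abc_hits, neighborhoods,
    ledger) where the ledger maps out exactly what curation must select.
    """
    rng = np.random.default_rng(cfg.seed + 17 if seed is None else seed)
    genomes = list(presence["strain"])
    erm_pos = set(presence.loc[presence["erm"] == 1, "strain"])
    abc_pos = set(presence.loc[presence["abc"] == 1, "strain"])

    erm_rows, abc_rows, nbr_rows = [], [], []
    expected_erm, expected_abc = [], {}

    negatives = [g for g in genomes if g not in erm_pos]
    rng.shuffle(negatives)
    sub_decoys = set(negatives[: cfg.decoy_subthreshold])
    ksga_decoys = set(
        negatives[cfg.decoy_subthreshold : cfg.decoy_subthreshold + cfg.decoy_ksga]
    )

    for g in genomes:
        strip = [str(p) for p in rng.choice(_NEUTRAL_PRODUCTS, size=9)]
        gene_ids = [f"{g}_g{i + 1:02d}" for i in range(len(strip))]
        focus = 4  # 0-based position of the focal gene in the strip

        if g in erm_pos:
            gene_ids[focus] = f"{g}_erm"
            strip[focus] = "rRNA adenine methyltransferase, Erm family"
            ident = float(rng.uniform(40.0, 80.0))
            erm_rows.append(_hit(g, gene_ids[focus], ident, rng))
            expected_erm.append(gene_ids[focus])
        elif g in sub_decoys:
            gene_ids[focus] = f"{g}_mtase"
            strip[focus] = "SAM-dependent methyltransferase"
            ident = float(rng.uniform(20.0, 34.5))
            erm_rows.append(_hit(g, gene_ids[focus], ident, rng))
        elif g in ksga_decoys:
            gene_ids[focus] = f"{g}_ksga"
            strip[focus] = "dimethyladenosine transferase KsgA"
            strip[focus - 1] = _KSGA_NEIGHBOR_PRODUCTS[0]
            strip[focus + 1] = _KSGA_NEIGHBOR_PRODUCTS[1]
            strip[focus + 2] = _KSGA_NEIGHBOR_PRODUCTS[2]
            ident = float(rng.uniform(36.0, 45.0))  # above threshold: context must catch it
            erm_rows.append(_hit(g, gene_ids[focus], ident, rng))

        if g in abc_pos:
            best_id = f"{g}_abc1"
            best_score = float(rng.uniform(300.0, 500.0))
            abc_rows.append(
                _hit(g, best_id, rng.uniform(40.0, 70.0), rng, positives=rng.uniform(55.0, 90.0), score=best_score)
            )
            abc_rows.append(
                _hit(g, f"{g}_abc2", rng.uniform(30.0, 40.0), rng, positives=rng.uniform(41.0, 54.0), score=best_score - rng.uniform(20.0, 100.0))
            )
            abc_rows.append(
                _hit(g, f"{g}_abc3", rng.uniform(15.0, 25.0), rng, positives=rng.uniform(20.0, 39.0), score=rng.uniform(50.0, 150.0))
            )
            expected_abc[g] = best_id

        for i, (gid, product) in enumerate(zip(gene_ids, strip)):
            nbr_rows.append(
                {"genome": g, "gene_id": gid, "position_index": i + 1, "product": product}
            )

    erm_hits = pd.DataFrame(
        erm_rows, columns=["genome", "subject_id", "pct_identity", "pct_positives", "bitscore"]
    )
    abc_hits = pd.DataFrame(
        abc_rows, columns=["genome", "subject_id", "pct_identity", "pct_positives", "bitscore"]
    )
    neighborhoods = pd.DataFrame(nbr_rows)
    ledger = {
        "erm_expected_subjects": sorted(expected_erm),
        "erm_expected_genomes": sorted(erm_pos),
        "abc_expected_best": expected_abc,
        "abc_expected_genomes": sorted(abc_pos),
        "both_expected_genomes": sorted(erm_pos & abc_pos),
        "decoys_subthreshold": sorted(sub_decoys),
        "decoys_ksga": sorted(ksga_decoys),
    }
    return erm_hits, abc_hits, neighborhoods, ledger


def _hit(genome, subject, identity, rng, positives=None, score=None):
    identity = float(identity)
    if positives is None:
        positives = min(identity + float(rng.uniform(5.0, 15.0)), 100.0)
    if score is None:
        score = float(rng.uniform(150.0, 400.0))
    return {
        "genome": genome,
        "subject_id": subject,
        "pct_identity": round(identity, 1),
        "pct_positives": round(float(positives), 1),
        "bitscore": round(float(score), 1),
    }


# ---------------------------------------------------------------------------
# whole-dataset orchestration


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one complete synthetic dataset from a single seed."""
    rng = np.random.default_rng(cfg.seed)
    sub = iter(rng.integers(0, _SEED_CAP, size=32).tolist())

    species = simulate_species_tree(cfg, seed=next(sub))
    labels = [lf.taxon.label for lf in species.leaf_node_iter()]

    gene_trees, gene_alignments = {}, {}
    for gene in ("erm", "abc"):
        gtree = apply_hgt(species, cfg.hgt_for(gene), seed=next(sub))
        gene_trees[gene] = gtree
        gene_alignments[gene] = evolve_alignment(
            gtree, "JTT", cfg.seq_length_aa, next(sub), rate=cfg.protein_rate
        )
    marker = evolve_alignment(
        species, "JC69", cfg.seq_length_nt, next(sub), rate=cfg.marker_rate
    )

    housekeeping = {}
    drop_rng = np.random.default_rng(next(sub))
    missing = {}
    if cfg.n_missing_housekeeping:
        victims = drop_rng.choice(labels, size=cfg.n_missing_housekeeping, replace=False)
        genes = drop_rng.choice(len(DEFAULT_GENES), size=cfg.n_missing_housekeeping)
        for strain, gi in zip(victims, genes):
            missing.setdefault(DEFAULT_GENES[gi], []).append(str(strain))
    for gene in DEFAULT_GENES:
        aln = evolve_alignment(
            species, "JTT", cfg.seq_length_aa, next(sub), rate=cfg.protein_rate
        )
        gone = set(missing.get(gene, ()))
        if gone:
            keep = [i for i, lab in enumerate(aln.labels) if lab not in gone]
            aln = Alignment(
                tuple(aln.labels[i] for i in keep),
                tuple(aln.rows[i] for i in keep),
                PROTEIN,
            )
        housekeeping[gene] = aln

    presence, true_table = simulate_presence(cfg, labels=labels, seed=next(sub))
    phenotype = simulate_phenotype(cfg, presence, seed=next(sub))
    environment = simulate_environment(species, cfg, seed=next(sub))
    erm_hits, abc_hits, neighborhoods, hit_ledger = emit_hit_tables(
        cfg, presence, seed=next(sub)
    )

    tag_rng = np.random.default_rng(next(sub))
    k = int(round(cfg.subgroup_fraction * cfg.n_taxa))
    subgroup = sorted(tag_rng.choice(labels, size=k, replace=False).tolist())

    retained_mls = set(labels)
    for gene in DEFAULT_GENES:
        retained_mls &= set(housekeeping[gene].labels)

    ledger = {
        "true_presence_table": true_table,
        "species_tree_height": tree_height(species),
        "hgt_events": {g: cfg.hgt_for(g) for g in ("erm", "abc")},
        "missing_housekeeping": {g: sorted(v) for g, v in missing.items()},
        "mls_retained_strains": sorted(retained_mls),
        "n_mls_retained": len(retained_mls),
        "subgroup": subgroup,
        **hit_ledger,
    }
    return SimulatedDataset(
        config=cfg,
        species_tree=species,
        gene_trees=gene_trees,
        marker_alignment=marker,
        gene_alignments=gene_alignments,
        housekeeping_alignments=housekeeping,
        presence=presence,
        phenotype=phenotype,
        site_metadata=environment,
        erm_hits=erm_hits,
        abc_hits=abc_hits,
        neighborhoods=neighborhoods,
        subgroup=subgroup,
        ledger=ledger,
    )
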