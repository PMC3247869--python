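"""Synthetic pangenome generator.

Emulates the statistical structure every scorer assumes, so the whole
toolbox is testable end to end without downloads:

* a random binary phylogeny over reference organisms; each target gene's
  presence/absence evolves down it as a two-state gain/loss process, so
  related organisms have correlated profiles;
* disjoint functional modules whose member genes share correlated presence
  (co-presence boost), are co-located in the genomes on the same strand
  with small intergenic gaps (when flagged), and occasionally appear fused
  into a single reference gene;
* per-organism circular genomes with gene order, coordinates and strands,
  including filler genes without target homologs (reference genomes carry
  genes beyond target orthologs);
* a homology table (E-values drawn below the homology threshold for present
  orthologs, nothing otherwise — sparse, like a real BLAST table), genome
  annotations, and a gold standard whose positives are exactly the
  within-module pairs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .iokit import (GeneRecord, HomologyHit, PairLabel, RepliconInfo,
                    ScoreMatrix, write_annotation, write_homology_table,
                    write_pair_labels)

__all__ = ["SimulationParams", "SyntheticWorld", "simulate_world",
           "planted_bias_matrix", "PRESETS"]


@dataclass(frozen=True)
class SimulationParams:
    n_organisms: int = 30
    n_genes: int = 60
    n_modules: int = 8
    module_size: int = 4
    presence_rate: float = 0.65     # stationary probability of presence
    rate_spread: float = 0.10       # per-gene spread of the base rate
    gain_loss_rate: float = 0.8     # switching intensity per unit branch
    co_presence_boost: float = 0.85 # P(member copies the module pattern)
    co_location_prob: float = 0.75  # fraction of modules placed contiguously
    fusion_rate: float = 0.0        # fraction of modules with a fused form
    fusion_per_org: float = 0.5     # P(fused gene emitted | both present)
    noise_rate: float = 0.02        # random presence bit flips
    extra_genes: float = 1.0        # filler genes per genome / n_genes
    gap_scale: float = 1.0          # multiplies intergenic gap sizes
    label_noise: float = 0.0        # fraction of gold-standard errors:
                                    # positives dropped to negative and an
                                    # equal number of spurious positives
                                    # (emulates incomplete curation)

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules cannot cover more genes than exist")


PRESETS: dict[str, SimulationParams] = {
    "small": SimulationParams(),
    # calibration world: no modules, and genomes padded with filler genes to
    # realistic bacterial sizes (~1800 genes) so the discrete rank-distance
    # null is close to its continuous uniform limit
    "null": SimulationParams(n_genes=72, n_modules=0, module_size=1,
                             co_presence_boost=0.0, co_location_prob=0.0,
                             fusion_rate=0.0, noise_rate=0.0,
                             extra_genes=24.0),
    "biased": SimulationParams(rate_spread=0.25),
    "fusion-rich": SimulationParams(fusion_rate=0.6),
}


@dataclass
class SyntheticWorld:
    params: SimulationParams
    seed: int
    organisms: list[str]
    genes: list[str]
    bits: np.ndarray                      # genes x organisms presence
    modules: list[list[str]]
    colocated: list[bool]
    hits: list[HomologyHit]
    ref_genes: list[GeneRecord]
    ref_replicons: list[RepliconInfo]
    target_genes: list[GeneRecord]
    target_replicons: list[RepliconInfo]
    labels: dict[frozenset, int]
    tree_children: list[tuple[int, int]] = field(default_factory=list)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        write_homology_table(self.hits, os.path.join(out_dir, "homology.tsv"))
        write_annotation(self.ref_genes, self.ref_replicons,
                         os.path.join(out_dir, "reference.ann.tsv"))
        write_annotation(self.target_genes, self.target_replicons,
                         os.path.join(out_dir, "target.ann.tsv"))
        pls = [PairLabel(*sorted(k), label=v) for k, v in
               sorted(self.labels.items(), key=lambda kv: sorted(kv[0]))]
        write_pair_labels(pls, os.path.join(out_dir, "gold.tsv"))
        with open(os.path.join(out_dir, "organisms.txt"), "w") as fh:
            for o in self.organisms:
                fh.write(o + "\n")


def _random_phylogeny(n: int, rng) -> tuple[list[tuple[int, int]], list[float]]:
    """Random binary tree over n leaves by successive random joins;
    exponential branch lengths.  Returns (children per internal node,
    branch length to each node's parent, indexed by node id)."""
    nodes = list(range(n))
    children: list[tuple[int, int]] = []
    lengths = list(rng.exponential(0.5, size=2 * n - 1))
    next_id = n
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [x for x in nodes if x not in (a, b)] + [next_id]
        children.append((a, b))
        next_id += 1
    return children, lengths


def _evolve_pattern(children, lengths, n_leaves: int, pi: float,
                    nu: float, rng) -> np.ndarray:
    """Two-state gain/loss process down the tree: a child copies its parent
    with probability exp(-nu * branch), else re-draws Bernoulli(pi)."""
    n_nodes = n_leaves + len(children)
    state = np.empty(n_nodes, dtype=np.uint8)
    root = n_nodes - 1
    state[root] = rng.random() < pi
    for k in range(len(children) - 1, -1, -1):
        parent = n_leaves + k
        for child in children[k]:
            if rng.random() < np.exp(-nu * lengths[child]):
                state[child] = state[parent]
            else:
                state[child] = rng.random() < pi
    return state[:n_leaves]


def simulate_world(params: SimulationParams | None = None,
                   seed: int = 0) -> SyntheticWorld:
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    P = params

    organisms = [f"org{i:03d}" for i in range(P.n_organisms)]
    genes = [f"g{i:03d}" for i in range(P.n_genes)]
    children, lengths = _random_phylogeny(P.n_organisms, rng)

    # modules: disjoint leading blocks of the gene list
    modules = [genes[m * P.module_size:(m + 1) * P.module_size]
               for m in range(P.n_modules)]
    colocated = [bool(rng.random() < P.co_location_prob) for _ in modules]
    fused = [bool(rng.random() < P.fusion_rate) for _ in modules]
    module_of = {g: m for m, mod in enumerate(modules) for g in mod}

    # presence/absence: per-gene gain/loss down the tree; module members
    # copy a shared latent pattern with probability co_presence_boost
    base_rates = np.clip(
        rng.uniform(P.presence_rate - P.rate_spread,
                    P.presence_rate + P.rate_spread, size=P.n_genes),
        0.05, 0.95)
    latent = [_evolve_pattern(children, lengths, P.n_organisms,
                              P.presence_rate, P.gain_loss_rate, rng)
              for _ in modules]
    bits = np.zeros((P.n_genes, P.n_organisms), dtype=np.uint8)
    for gi, g in enumerate(genes):
        own = _evolve_pattern(children, lengths, P.n_organisms,
                              base_rates[gi], P.gain_loss_rate, rng)
        if g in module_of and P.co_presence_boost > 0:
            share = rng.random(P.n_organisms) < P.co_presence_boost
            bits[gi] = np.where(share, latent[module_of[g]], own)
        else:
            bits[gi] = own
    if P.noise_rate > 0:
        flips = rng.random(bits.shape) < P.noise_rate
        bits = bits ^ flips.astype(np.uint8)

    hits: list[HomologyHit] = []
    ref_genes: list[GeneRecord] = []
    ref_replicons: list[RepliconInfo] = []

    def log_uniform_e(n: int) -> np.ndarray:
        return 10.0 ** rng.uniform(-30, -6, size=n)

    def layout(org: str, entries: list[tuple[str, str]],
               tight: set[str]) -> tuple[list[GeneRecord], RepliconInfo]:
        """Assign coordinates/strands to an ordered gene list; genes in
        ``tight`` use small gaps to the *following* gene."""
        recs: list[GeneRecord] = []
        pos = 1
        for rank, (name, strand) in enumerate(entries, start=1):
            length = int(rng.integers(300, 1500))
            recs.append(GeneRecord(name, org, f"{org}:chr", pos,
                                   pos + length - 1, strand, rank))
            gap = int(rng.integers(5, 40)) if name in tight else \
                int(rng.integers(50, 300) * P.gap_scale)
            pos += length + max(gap, 1)
        rep = RepliconInfo(f"{org}:chr", org, pos + 100, circular=True)
        return recs, rep

    def ordered_entries(present: list[str], org: str) -> tuple[list[tuple[str, str]], set[str]]:
        """Shuffle genes, then place each co-located module's present
        members as a contiguous same-strand block."""
        loose = [g for g in present
                 if module_of.get(g) is None or not colocated[module_of[g]]]
        blocks: list[list[str]] = []
        for m, mod in enumerate(modules):
            if not colocated[m]:
                continue
            members = [g for g in mod if g in present]
            if members:
                blocks.append(members)
        items: list[object] = list(loose)
        rng.shuffle(items)
        for blk in blocks:
            items.insert(int(rng.integers(0, len(items) + 1)), blk)
        entries: list[tuple[str, str]] = []
        tight: set[str] = set()
        for it in items:
            if isinstance(it, list):
                strand = "+" if rng.random() < 0.5 else "-"
                for g in it[:-1]:
                    tight.add(f"{org}:{g}" if org != "TARGET" else g)
                entries.extend((f"{org}:{g}" if org != "TARGET" else g, strand)
                               for g in it)
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                entries.append((f"{org}:{it}" if org != "TARGET" else it, strand))
        return entries, tight

    n_filler = int(round(P.extra_genes * P.n_genes))
    for oi, org in enumerate(organisms):
        present = [genes[gi] for gi in range(P.n_genes) if bits[gi, oi]]
        entries, tight = ordered_entries(present, org)
        fillers = [(f"{org}:x{k}", "+" if rng.random() < 0.5 else "-")
                   for k in range(n_filler)]
        for f in fillers:
            entries.insert(int(rng.integers(0, len(entries) + 1)), f)
        # fused forms: one reference gene hit by both module partners
        fusion_hits: list[tuple[str, str]] = []
        for m, mod in enumerate(modules):
            if not fused[m]:
                continue
            a, b = mod[0], mod[1]
            if a in present and b in present and rng.random() < P.fusion_per_org:
                fname = f"{org}:fus{m}"
                entries.insert(int(rng.integers(0, len(entries) + 1)),
                               (fname, "+"))
                fusion_hits.extend([(a, fname), (b, fname)])
        recs, rep = layout(org, entries, tight)
        ref_genes.extend(recs)
        ref_replicons.append(rep)
        evals = log_uniform_e(len(present))
        for g, e in zip(present, evals):
            hits.append(HomologyHit(g, org, f"{org}:{g}", float(e),
                                    float(rng.uniform(70, 100))))
        for g, fname in fusion_hits:
            hits.append(HomologyHit(g, org, fname,
                                    float(log_uniform_e(1)[0]),
                                    float(rng.uniform(55, 95))))

    # the target genome itself: all genes present, modules co-located
    t_entries, t_tight = ordered_entries(genes, "TARGET")
    target_recs, target_rep = layout("TARGET", t_entries, t_tight)

    labels: dict[frozenset, int] = {}
    for i in range(P.n_genes):
        for j in range(i + 1, P.n_genes):
            a, b = genes[i], genes[j]
            pos = (module_of.get(a) is not None
                   and module_of.get(a) == module_of.get(b))
            labels[frozenset((a, b))] = int(pos)
    if P.label_noise > 0:
        pos_keys = [k for k, v in labels.items() if v == 1]
        neg_keys = [k for k, v in labels.items() if v == 0]
        n_flip = int(round(P.label_noise * len(pos_keys)))
        for idx in rng.choice(len(pos_keys), size=n_flip, replace=False):
            labels[pos_keys[idx]] = 0
        for idx in rng.choice(len(neg_keys), size=n_flip, replace=False):
            labels[neg_keys[idx]] = 1

    world = SyntheticWorld(P, seed, organisms, genes, bits, modules,
                           colocated, hits, ref_genes, ref_replicons,
                           target_recs, [target_rep], labels, children)
    return world


def planted_bias_matrix(n_genes: int = 200, bias_spread: float = 2.0,
                        n_positive: int = 150, signal: float = 1.0,
                        noise_sd: float = 0.5, seed: int = 0
                        ) -> tuple[ScoreMatrix, dict[frozenset, int]]:
    """Score matrix with additive per-gene bias and planted positives:
    score(i, j) = b_i + b_j + signal * 1[positive] + noise.  Exercises the
    bias model the row normalizations are built to remove."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    b = rng.normal(0.0, bias_spread, size=n_genes)
    values = b[:, None] + b[None, :]
    iu = np.triu_indices(n_genes, k=1)
    n_pairs = iu[0].size
    pos_idx = rng.choice(n_pairs, size=n_positive, replace=False)
    pos_mask = np.zeros(n_pairs, dtype=bool)
    pos_mask[pos_idx] = True
    noise = rng.normal(0.0, noise_sd, size=n_pairs)
    upper = values[iu] + signal * pos_mask + noise
    values[iu] = upper
    values[(iu[1], iu[0])] = upper
    np.fill_diagonal(values, np.nan)
    labels = {frozenset((genes[i], genes[j])): int(p)
              for i, j, p in zip(iu[0], iu[1], pos_mask)}
    return ScoreMatrix(genes, values, method="planted-bias"), labels
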