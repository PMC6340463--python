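"""Synthetic phylotranscriptomic datasets with known ground truth.

The generator emulates the statistical structure of a codon-alignment
dataset from a rapid radiation: gene trees drawn under the multispecies
coalescent over a species tree with short internal branches (hence
substantial incomplete lineage sorting), codon sequences carrying
background synonymous and nonsynonymous variation, an optional set of
injected group-diagnostic nonsynonymous sites in a non-monophyletic
focal group, and per-taxon missing data.

The default species tree mirrors a nine-taxon tuna-like radiation: an
outgroup (skipjack), an eight-species ingroup in which the three
"bluefin" species are paraphyletic (a warm-water clade is nested
between them), internal branches of 0.5-1 coalescent units, and the
focal/required groups of the parallel-selection scan pre-configured to
the bluefin contrast.

Background sequence evolution places Poisson-distributed
single-nucleotide mutations on the realized gene-tree branches over a
random stop-free ancestral CDS; each species' emitted sequence is the
fixed-nucleotide consensus of its sampled chromosomes (sites still
segregating within a species come out as missing, as they would in
real genotype calls). Injected sites overwrite one codon so that
exactly the focal species share a nonsynonymous state.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .coalescent import Genealogy, MSCSimulator, derive_seed
from .prep import GeneTreeRecord, GeneTreeSet
from .selection import (
    _aa_lookup,
    CodonAlignmentSet,
    GroupSpec,
    IUPAC_PAIR,
)
from .trees import SpeciesTreeCU, get_convention

__all__ = [
    "DEFAULT_SPECIES_TREE",
    "SynthConfig",
    "InjectedSite",
    "TruthTable",
    "SyntheticDataset",
    "generate_dataset",
    "emit_individuals",
]

#: Nine-taxon radiation used as the default simulation condition: the
#: three bluefin species are non-monophyletic (the warm-water clade is
#: their sister group's neighbour), internal branches are short enough
#: for heavy gene-tree discordance, and skipjack is the outgroup.
#: Lengths are coalescent units on the SNAQ scale (generations / Ne).
DEFAULT_SPECIES_TREE = (
    "(skipjack:12.0,(albacore:7.0,(southern_bluefin:6.0,"
    "((pacific_bluefin:5.0,atlantic_bluefin:5.0):1.0,"
    "(bigeye:4.0,(yellowfin:3.5,(longtail:3.0,blackfin:3.0):0.5):0.5):1.0)"
    ":0.5):0.5):5.0);"
)

DEFAULT_FOCAL = ("atlantic_bluefin", "pacific_bluefin", "southern_bluefin")
DEFAULT_REQUIRED = ("albacore",)

_BASES = "ACGT"


@dataclass
class SynthConfig:
    """Full description of one synthetic dataset.

    ``mutation_rate`` is per nucleotide site per coalescent unit on the
    ms scale (4 Ne generations), applied along gene-tree branches.
    """

    species_tree_newick: str = DEFAULT_SPECIES_TREE
    units: str = "SNAQ"
    n_genes: int = 400
    codons_per_gene: int = 80
    mutation_rate: float = 0.01
    chromosomes_per_species: int = 2
    focal_group: Tuple[str, ...] = DEFAULT_FOCAL
    required_present: Tuple[str, ...] = DEFAULT_REQUIRED
    max_missing: int = 2
    n_injected_sites: int = 0
    injected_genes: Optional[Tuple[str, ...]] = None
    missingness_rate: float = 0.02
    heterozygosity: float = 0.005
    individuals_per_species: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "missingness_rate", "heterozygosity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_injected_sites > self.n_genes * self.codons_per_gene:
            raise ValueError("more injected sites than codon sites")
        if self.chromosomes_per_species < 1:
            raise ValueError("chromosomes_per_species must be >= 1")

    def species_tree(self) -> SpeciesTreeCU:
        return SpeciesTreeCU.from_newick(
            self.species_tree_newick, units=get_convention(self.units)
        )

    def group_spec(self) -> GroupSpec:
        return GroupSpec(
            focal=self.focal_group,
            required_present=self.required_present,
            max_missing=self.max_missing,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SynthConfig":
        data = yaml.safe_load(text)
        for key in ("focal_group", "required_present", "injected_genes"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class InjectedSite:
    gene: str
    codon_index: int
    focal_aa: str
    background_aa: str
    masked_species: frozenset = frozenset()


@dataclass
class TruthTable:
    injected: list[InjectedSite]
    genealogies: Dict[str, Genealogy] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["gene\tcodon_index\tfocal_aa\tbackground_aa\tmasked_species"]
        for s in self.injected:
            lines.append(
                f"{s.gene}\t{s.codon_index}\t{s.focal_aa}\t{s.background_aa}\t"
                + (",".join(sorted(s.masked_species)) if s.masked_species else ".")
            )
        return "\n".join(lines) + "\n"


@dataclass
class SyntheticDataset:
    config: SynthConfig
    species_tree: SpeciesTreeCU
    alignments: CodonAlignmentSet
    gene_trees: GeneTreeSet
    truth: TruthTable

    def write(self, directory: Union[str, Path]) -> None:
        """FASTA per gene, multi-newick gene trees, species tree, truth
        table, and the generating config, for provenance."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.alignments.write_fasta_dir(directory / "alignments")
        with open(directory / "gene_trees.nwk", "w") as fh:
            for rec in self.gene_trees.records:
                fh.write(
                    rec.tree.as_string(schema="newick", suppress_rooting=True).strip()
                    + "\n"
                )
        with open(directory / "species_tree.nwk", "w") as fh:
            fh.write(
                self.species_tree.tree.as_string(
                    schema="newick", suppress_rooting=True
                ).strip()
                + "\n"
            )
        with open(directory / "truth.tsv", "w") as fh:
            fh.write(self.truth.to_tsv())
        with open(directory / "config.yaml", "w") as fh:
            fh.write(self.config.to_yaml())


def _stop_free_ancestral(rng: np.random.Generator, n_codons: int, lut: np.ndarray) -> np.ndarray:
    seq = rng.integers(0, 4, size=3 * n_codons, dtype=np.uint8)
    while True:
        codons = seq.reshape(n_codons, 3)
        idx = codons[:, 0].astype(np.int16) * 16 + codons[:, 1] * 4 + codons[:, 2]
        stops = np.nonzero(lut[idx] == ord("*"))[0]
        if stops.size == 0:
            return seq
        for c in stops:
            seq[3 * c : 3 * c + 3] = rng.integers(0, 4, size=3, dtype=np.uint8)


def _tips_per_edge(g: Genealogy) -> list[np.ndarray]:
    out = []
    for child in g.edge_child:
        mask = g.node_mask[child]
        out.append(
            np.array([i for i in range(g.n_tips) if mask >> i & 1], dtype=np.int64)
        )
    return out


def _evolve_gene(
    g: Genealogy,
    n_codons: int,
    mutation_rate: float,
    rng: np.random.Generator,
    lut: np.ndarray,
) -> np.ndarray:
    """Chromosome-level sequences (n_tips x 3*n_codons, base codes 0-3).

    Mutations are applied ancestor-first (lower edge indices are always
    descendants of higher ones along any lineage); codons that acquire a
    stop anywhere are re-drawn by re-running their own mutations with
    fresh derived bases, or reverted if a stop persists.
    """
    n_sites = 3 * n_codons
    ancestral = _stop_free_ancestral(rng, n_codons, lut)
    seqs = np.tile(ancestral, (g.n_tips, 1))
    lengths = np.array(g.edge_length)
    total = float(lengths.sum())
    k = rng.poisson(mutation_rate * total * n_sites)
    if k == 0:
        return seqs
    sites = rng.integers(0, n_sites, size=k)
    edges = np.searchsorted(np.cumsum(lengths), rng.random(k) * total)
    edges = np.minimum(edges, len(lengths) - 1)
    tips_per_edge = _tips_per_edge(g)

    by_codon: Dict[int, list[tuple[int, int]]] = {}
    for s, e in zip(sites.tolist(), edges.tolist()):
        by_codon.setdefault(s // 3, []).append((e, s))

    def apply_codon(codon: int) -> None:
        cols = slice(3 * codon, 3 * codon + 3)
        seqs[:, cols] = np.tile(ancestral[cols], (g.n_tips, 1))
        for e, s in sorted(by_codon[codon], reverse=True):  # ancestors first
            tips = tips_per_edge[e]
            cur = seqs[tips[0], s]
            seqs[tips, s] = (cur + 1 + rng.integers(0, 3)) % 4

    for codon in by_codon:
        apply_codon(codon)
    # stop-codon rejection, per affected codon only
    for _ in range(30):
        codons = seqs.reshape(g.n_tips, n_codons, 3)
        idx = (
            codons[:, :, 0].astype(np.int16) * 16
            + codons[:, :, 1] * 4
            + codons[:, :, 2]
        )
        stop_codons = sorted(set(np.nonzero((lut[idx] == ord("*")).any(axis=0))[0].tolist()))
        stop_codons = [c for c in stop_codons if c in by_codon]
        if not stop_codons:
            break
        for c in stop_codons:
            apply_codon(c)
    else:
        stop_codons = []
    # revert any codon that still carries a stop (mutation discarded)
    codons = seqs.reshape(g.n_tips, n_codons, 3)
    idx = (
        codons[:, :, 0].astype(np.int16) * 16
        + codons[:, :, 1] * 4
        + codons[:, :, 2]
    )
    bad = np.nonzero((lut[idx] == ord("*")).any(axis=0))[0]
    for c in bad:
        seqs[:, 3 * c : 3 * c + 3] = ancestral[3 * c : 3 * c + 3]
    return seqs


def _species_consensus(
    seqs: np.ndarray, chrom_species: Sequence[str], species: Sequence[str]
) -> np.ndarray:
    """Fixed-nucleotide consensus per species (code 4 = missing)."""
    n_sites = seqs.shape[1]
    out = np.full((len(species), n_sites), 4, dtype=np.uint8)
    for row, sp in enumerate(species):
        rows = [i for i, s in enumerate(chrom_species) if s == sp]
        block = seqs[rows]
        fixed = (block == block[0]).all(axis=0)
        out[row, fixed] = block[0, fixed]
    return out


def _distinct_aa_codon_pair(
    rng: np.random.Generator, lut: np.ndarray
) -> tuple[np.ndarray, np.ndarray, str, str]:
    while True:
        a, b = rng.integers(0, 64, size=2)
        aa_a, aa_b = chr(lut[a]), chr(lut[b])
        if "*" in (aa_a, aa_b) or aa_a == aa_b:
            continue
        dec = lambda x: np.array([x // 16, (x // 4) % 4, x % 4], dtype=np.uint8)
        return dec(int(a)), dec(int(b)), aa_a, aa_b


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate alignments, gene trees and truth table from one config.

    Identical configs produce byte-identical outputs.
    """
    species_tree = config.species_tree()
    all_species = species_tree.species()
    if set(config.focal_group) >= set(all_species):
        raise ValueError("focal group covers every species")
    sim = MSCSimulator(species_tree, sample=config.chromosomes_per_species)
    species = sorted(set(sim.chrom_species))
    lut = _aa_lookup("Standard")
    n_codons = config.codons_per_gene

    gene_ids = [f"g{gi + 1:04d}" for gi in range(config.n_genes)]
    genes: Dict[str, Dict[str, str]] = {}
    records: list[GeneTreeRecord] = []
    genealogies: Dict[str, Genealogy] = {}
    consensus: Dict[str, np.ndarray] = {}

    for gi, gene in enumerate(gene_ids):
        rand = random.Random(derive_seed(config.seed, gi, 0))
        rng = np.random.default_rng(derive_seed(config.seed, gi, 1))
        g = sim._sim_genealogy(rand)
        genealogies[gene] = g
        seqs = _evolve_gene(g, n_codons, config.mutation_rate, rng, lut)
        consensus[gene] = _species_consensus(seqs, g.tip_species, species)
        records.append(GeneTreeRecord(gene, gene, g.to_dendropy()))

    top_rng = np.random.default_rng(derive_seed(config.seed, config.n_genes, 2))

    # inject group-diagnostic nonsynonymous sites
    injected: list[InjectedSite] = []
    focal_rows = [species.index(s) for s in config.focal_group]
    other_rows = [i for i in range(len(species)) if species[i] not in config.focal_group]
    if config.n_injected_sites:
        if config.injected_genes is not None:
            targets = list(config.injected_genes)
            if len(targets) != config.n_injected_sites:
                raise ValueError("injected_genes length != n_injected_sites")
        else:
            if config.n_injected_sites <= config.n_genes:
                targets = [
                    gene_ids[i]
                    for i in top_rng.choice(
                        config.n_genes, config.n_injected_sites, replace=False
                    )
                ]
            else:
                targets = [
                    gene_ids[i]
                    for i in top_rng.integers(0, config.n_genes, config.n_injected_sites)
                ]
        for gene in targets:
            c = int(top_rng.integers(0, n_codons))
            codon_x, codon_y, aa_x, aa_y = _distinct_aa_codon_pair(top_rng, lut)
            block = consensus[gene]
            for r in focal_rows:
                block[r, 3 * c : 3 * c + 3] = codon_x
            for r in other_rows:
                block[r, 3 * c : 3 * c + 3] = codon_y
            injected.append(InjectedSite(gene, c, aa_x, aa_y))

    # per-taxon missingness, codon-granular
    if config.missingness_rate > 0:
        for gene in gene_ids:
            block = consensus[gene]
            mask = (
                top_rng.random((len(species), n_codons)) < config.missingness_rate
            )
            rows, cols = np.nonzero(mask)
            for r, c in zip(rows, cols):
                block[r, 3 * c : 3 * c + 3] = 4
            for site in injected:
                if site.gene == gene:
                    masked = {
                        species[r]
                        for r in np.nonzero(mask[:, site.codon_index])[0]
                    }
                    if masked:
                        site.masked_species = frozenset(masked)

    alphabet = np.frombuffer(b"ACGTN", dtype=np.uint8)
    genes = {
        gene: {
            sp: alphabet[consensus[gene][row]].tobytes().decode()
            for row, sp in enumerate(species)
        }
        for gene in gene_ids
    }

    tip_map = {label: sp for label, sp in zip(sim.chromosomes, sim.chrom_species)}
    gene_trees = GeneTreeSet(records=records, tip_map=tip_map, outgroup="skipjack" if "skipjack" in species else None)
    return SyntheticDataset(
        config=config,
        species_tree=species_tree,
        alignments=CodonAlignmentSet(genes),
        gene_trees=gene_trees,
        truth=TruthTable(injected=injected, genealogies=genealogies),
    )


def emit_individuals(
    species_seqs: Dict[str, str],
    heterozygosity: float = 0.005,
    individuals_per_species: int = 2,
    seed: int = 0,
) -> Dict[str, str]:
    """Per-individual sequences with IUPAC heterozygote codes.

    Each individual copies its species sequence; at rate
    ``heterozygosity`` a resolved base is replaced by the two-base IUPAC
    code pairing it with a random different base. Collapsing the
    individuals back through the fixed-nucleotide rule recovers the
    species consensus except at heterozygous or missing positions.
    """
    if individuals_per_species < 1:
        raise ValueError("individuals_per_species must be >= 1")
    if not 0.0 <= heterozygosity <= 1.0:
        raise ValueError("heterozygosity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: Dict[str, str] = {}
    for sp in sorted(species_seqs):
        seq = species_seqs[sp].upper()
        for k in range(individuals_per_species):
            chars = list(seq)
            for i, ch in enumerate(chars):
                if ch in _BASES and rng.random() < heterozygosity:
                    other = _BASES[int(rng.integers(0, 4))]
                    while other == ch:
                        other = _BASES[int(rng.integers(0, 4))]
                    chars[i] = IUPAC_PAIR[frozenset((ch, other))]
            out[f"{sp}_i{k + 1}"] = "".join(chars)
    return out
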