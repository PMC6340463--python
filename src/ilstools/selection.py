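"""Phylogenetic scan for parallel selection on standing variation (PhyloGWAS).

The scan asks whether species that share a phenotype but are *not*
monophyletic carry more shared, group-diagnostic nonsynonymous
substitutions than incomplete lineage sorting alone would produce.

Pipeline:

1. Species-level codon alignments are screened codon by codon. A site
   is testable when it has at most two distinct amino-acid states among
   non-missing species (more suggests multiple hits rather than sorting
   of one ancestral variant) and at most two missing taxa.
2. A testable site is a *shared substitution* when every focal-group
   species carries one amino acid, every non-missing species outside
   the group carries a different one, and all required species have
   data.
3. The null expectation comes from genes with a single segregating
   site simulated under the multispecies coalescent over the species
   tree, sampling two chromosomes per species (diploid); a simulated
   gene matches when its mutation splits the focal group cleanly from
   the rest, with within-species fixation. Sites with one or two
   missing taxa in the data are accommodated by re-matching the
   simulated patterns with those taxa ignored, weighted by how often
   each missingness configuration occurs among tested codons.
4. The excess P value compares the observed count against the null:
   either the proportion of simulated datasets (of size equal to the
   number of variable amino-acid sites tested) with at least the
   observed count, or the equivalent binomial tail on the estimated
   per-site pattern probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .coalescent import MSCSimulator, derive_seed
from .trees import SpeciesTreeCU

__all__ = [
    "CodonAlignmentSet",
    "GroupSpec",
    "CodonSiteClass",
    "SharedSite",
    "SharedSubstitutionReport",
    "ILSPatternProbability",
    "PhyloGWASResult",
    "fix_species_sequence",
    "classify_codon_site",
    "find_shared_substitutions",
    "estimate_ils_pattern_probability",
    "phylogwas_pvalue",
]

_MISSING = 255
_BASES = "ACGT"
_BASE_CODE = np.full(256, _MISSING, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_IUPAC = set("ACGTRYSWKMBDHVN-?acgtryswkmbdhvn")

#: IUPAC code for an unordered pair of bases
IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


_LUT_CACHE: Dict[int, np.ndarray] = {}


def _aa_lookup(table: Union[str, CodonTable.CodonTable] = "Standard") -> np.ndarray:
    """64-entry codon-index -> amino-acid byte table ('*' for stops)."""
    if isinstance(table, str):
        table = CodonTable.unambiguous_dna_by_name[table]
    if id(table) in _LUT_CACHE:
        return _LUT_CACHE[id(table)]
    lut = np.zeros(64, dtype=np.uint8)
    for i1, b1 in enumerate(_BASES):
        for i2, b2 in enumerate(_BASES):
            for i3, b3 in enumerate(_BASES):
                codon = b1 + b2 + b3
                aa = "*" if codon in table.stop_codons else table.forward_table[codon]
                lut[16 * i1 + 4 * i2 + i3] = ord(aa)
    _LUT_CACHE[id(table)] = lut
    return lut


def translate_codon(codon: str, table: Union[str, CodonTable.CodonTable] = "Standard") -> Optional[str]:
    """Amino acid for one codon, or None if the codon is not fully resolved.

    Gaps, Ns and IUPAC ambiguity codes all make the codon unresolved;
    characters outside the IUPAC alphabet raise.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    bad = set(codon) - _IUPAC
    if bad:
        raise ValueError(f"invalid codon characters: {sorted(bad)}")
    idx = 0
    for ch in codon:
        code = _BASE_CODE[ord(ch)]
        if code == _MISSING:
            return None
        idx = idx * 4 + int(code)
    return chr(_aa_lookup(table)[idx])


class CodonAlignmentSet:
    """Per-gene, species-level codon alignments.

    ``genes`` maps gene id -> (species -> codon-aligned CDS). Within a
    gene all sequences share a length divisible by 3; the reading frame
    starts at position 0. Missing data may appear as ``N``/``-``/``?``
    or any IUPAC ambiguity code (treated as missing at the codon level).
    """

    def __init__(self, genes: Mapping[str, Mapping[str, str]]):
        if not genes:
            raise ValueError("empty alignment set")
        self.genes: Dict[str, Dict[str, str]] = {}
        for gene, seqs in genes.items():
            if not seqs:
                raise ValueError(f"gene {gene!r} has no sequences")
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) != 1:
                raise ValueError(f"gene {gene!r}: unequal sequence lengths")
            (length,) = lengths
            if length % 3:
                raise ValueError(f"gene {gene!r}: length {length} not divisible by 3")
            self.genes[gene] = {sp: s.upper() for sp, s in seqs.items()}

    def species_universe(self) -> list[str]:
        out: set[str] = set()
        for seqs in self.genes.values():
            out |= set(seqs)
        return sorted(out)

    def __len__(self) -> int:
        return len(self.genes)

    # FASTA I/O: one file per gene, records named by species
    def write_fasta_dir(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for gene, seqs in sorted(self.genes.items()):
            with open(directory / f"{gene}.fasta", "w") as fh:
                for sp in sorted(seqs):
                    fh.write(f">{sp}\n{seqs[sp]}\n")

    @classmethod
    def read_fasta_dir(cls, directory: Union[str, Path]) -> "CodonAlignmentSet":
        from Bio import SeqIO

        directory = Path(directory)
        genes: Dict[str, Dict[str, str]] = {}
        for path in sorted(directory.glob("*.fasta")):
            genes[path.stem] = {
                rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
            }
        return cls(genes)


@dataclass(frozen=True, init=False)
class GroupSpec:
    """Focal phenotype group for the scan.

    ``focal`` species must all carry the shared amino acid;
    ``required_present`` species (focal species are always implicitly
    required) must have data at a counted site; up to ``max_missing``
    other taxa may be missing. ``contrast`` optionally limits which
    species participate in the must-differ condition (default: every
    species in the alignment universe).
    """

    focal: frozenset
    required_present: frozenset = frozenset()
    max_missing: int = 2
    contrast: Optional[frozenset] = None
    polarity: str = "either"

    def __init__(
        self,
        focal: Iterable[str],
        required_present: Iterable[str] = (),
        max_missing: int = 2,
        contrast: Optional[Iterable[str]] = None,
        polarity: str = "either",
    ) -> None:
        object.__setattr__(self, "focal", frozenset(focal))
        object.__setattr__(
            self, "required_present", frozenset(required_present) | self.focal
        )
        object.__setattr__(self, "max_missing", int(max_missing))
        object.__setattr__(
            self, "contrast", None if contrast is None else frozenset(contrast)
        )
        object.__setattr__(self, "polarity", polarity)
        if not self.focal:
            raise ValueError("focal group is empty")
        if self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")


@dataclass
class CodonSiteClass:
    """Classification of one codon column."""

    amino_acids: Dict[str, Optional[str]]
    n_states: int
    missing: frozenset
    retained: bool


def fix_species_sequence(individual_seqs: Sequence[str]) -> str:
    """Collapse per-individual CDS (IUPAC heterozygote codes allowed) to
    the species' fixed-nucleotide sequence.

    A position is fixed only when every non-missing individual carries
    the same unambiguous base; polymorphic, heterozygous or ambiguous
    positions are emitted as ``N``.
    """
    if not individual_seqs:
        raise ValueError("no individual sequences")
    lengths = {len(s) for s in individual_seqs}
    if len(lengths) != 1:
        raise ValueError("individual sequences differ in length")
    seqs = [s.upper() for s in individual_seqs]
    out = []
    for col in zip(*seqs):
        bad = set(col) - _IUPAC
        if bad:
            raise ValueError(f"invalid characters: {sorted(bad)}")
        states = {c for c in col if c not in "N-?"}
        if len(states) == 1 and next(iter(states)) in _BASES:
            out.append(next(iter(states)))
        else:
            out.append("N")
    return "".join(out)


def classify_codon_site(
    column: Mapping[str, str],
    table: Union[str, CodonTable.CodonTable] = "Standard",
    max_states: int = 2,
    max_missing: int = 2,
) -> CodonSiteClass:
    """Amino-acid states and filter decision for one codon column.

    A species whose codon contains a gap, N or ambiguity code is missing
    at the site. Retention requires at most ``max_states`` distinct
    amino acids among non-missing species and at most ``max_missing``
    missing taxa.
    """
    aas: Dict[str, Optional[str]] = {}
    for sp, codon in column.items():
        aas[sp] = translate_codon(codon, table)
    missing = frozenset(sp for sp, aa in aas.items() if aa is None)
    states = {aa for aa in aas.values() if aa is not None}
    retained = len(states) <= max_states and len(missing) <= max_missing
    return CodonSiteClass(aas, len(states), missing, retained)


@dataclass
class SharedSite:
    gene: str
    codon_index: int  # 0-based codon position within the gene
    focal_aa: str
    other_aa: str
    missing: frozenset


@dataclass
class SharedSubstitutionReport:
    sites: list[SharedSite]
    s_genes: int
    s_sites: int
    n_var: int
    missing_config_freqs: Dict[frozenset, float]
    group: GroupSpec

    def to_tsv(self) -> str:
        lines = ["gene\tcodon_index\tfocal_aa\tother_aa\tmissing_taxa"]
        for s in self.sites:
            lines.append(
                f"{s.gene}\t{s.codon_index}\t{s.focal_aa}\t{s.other_aa}\t"
                + (",".join(sorted(s.missing)) if s.missing else ".")
            )
        return "\n".join(lines) + "\n"


def _gene_matrices(
    seqs: Mapping[str, str], species: Sequence[str], lut: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(aa matrix, missing mask), shape (n_species, n_codons).

    Species absent from the gene are fully missing. Amino acids are
    byte codes; missing entries are 255.
    """
    length = len(next(iter(seqs.values())))
    n_codons = length // 3
    aa = np.full((len(species), n_codons), _MISSING, dtype=np.uint8)
    for row, sp in enumerate(species):
        if sp not in seqs:
            continue
        raw = np.frombuffer(seqs[sp].encode(), dtype=np.uint8)
        codes = _BASE_CODE[raw].reshape(n_codons, 3)
        ok = (codes != _MISSING).all(axis=1)
        idx = codes[:, 0].astype(np.int16) * 16 + codes[:, 1] * 4 + codes[:, 2]
        aa[row, ok] = lut[idx[ok]]
    return aa, aa == _MISSING


def find_shared_substitutions(
    alignments: CodonAlignmentSet,
    group: GroupSpec,
    table: Union[str, CodonTable.CodonTable] = "Standard",
) -> SharedSubstitutionReport:
    """Scan every codon site for group-diagnostic shared substitutions.

    Returns per-site records, the gene and site counts, the number of
    variable amino-acid sites tested (``n_var``: retained sites with two
    amino-acid states among non-missing species, whether or not they
    are species-diagnostic), and the frequency of each missing-taxa
    configuration among those tested sites.
    """
    species = alignments.species_universe()
    if group.contrast is not None:
        species = [s for s in species if s in group.contrast or s in group.focal]
    sp_index = {s: i for i, s in enumerate(species)}
    unknown = (group.focal | group.required_present) - set(sp_index)
    if unknown:
        raise ValueError(f"group species not in alignments: {sorted(unknown)}")
    focal_rows = np.array([sp_index[s] for s in sorted(group.focal)])
    required_rows = np.array([sp_index[s] for s in sorted(group.required_present)])
    other_rows = np.array(
        [i for s, i in sp_index.items() if s not in group.focal]
    )
    if other_rows.size == 0:
        raise ValueError("focal group covers every species; contrast undefined")

    lut = _aa_lookup(table)
    sites: list[SharedSite] = []
    n_var = 0
    config_counts: Dict[frozenset, int] = {}
    genes_hit: set[str] = set()

    for gene, seqs in alignments.genes.items():
        aa, miss = _gene_matrices(seqs, species, lut)
        n_missing = miss.sum(axis=0)
        nonmiss = ~miss
        lo = np.min(np.where(nonmiss, aa, _MISSING), axis=0)
        hi = np.max(np.where(nonmiss, aa, 0), axis=0)
        all_missing = ~nonmiss.any(axis=0)
        two_state_ok = (((aa == lo) | (aa == hi)) | miss).all(axis=0)
        retained = (n_missing <= group.max_missing) & two_state_ok & ~all_missing
        variable = retained & (lo != hi)
        var_cols = np.nonzero(variable)[0]
        if var_cols.size == 0:
            continue
        n_var += var_cols.size
        for c in var_cols:
            cfg = frozenset(species[i] for i in np.nonzero(miss[:, c])[0])
            config_counts[cfg] = config_counts.get(cfg, 0) + 1
        # diagnostic sites among the variable ones
        focal_aa = aa[focal_rows][:, var_cols]
        focal_ok = (focal_aa != _MISSING).all(axis=0) & (
            focal_aa == focal_aa[0]
        ).all(axis=0)
        required_ok = (aa[required_rows][:, var_cols] != _MISSING).all(axis=0)
        other_aa = aa[other_rows][:, var_cols]
        other_nonmiss = other_aa != _MISSING
        differs = (other_aa != focal_aa[0]) | ~other_nonmiss
        other_ok = differs.all(axis=0) & other_nonmiss.any(axis=0)
        hit = focal_ok & required_ok & other_ok
        for j in np.nonzero(hit)[0]:
            c = int(var_cols[j])
            x = chr(int(focal_aa[0, j]))
            col_other = other_aa[:, j]
            y = chr(int(col_other[col_other != _MISSING][0]))
            sites.append(
                SharedSite(
                    gene,
                    c,
                    x,
                    y,
                    frozenset(species[i] for i in np.nonzero(miss[:, c])[0]),
                )
            )
            genes_hit.add(gene)

    freqs = (
        {cfg: cnt / n_var for cfg, cnt in config_counts.items()} if n_var else {}
    )
    return SharedSubstitutionReport(
        sites=sites,
        s_genes=len(genes_hit),
        s_sites=len(sites),
        n_var=n_var,
        missing_config_freqs=freqs,
        group=group,
    )


# ---------------------------------------------------------------------------
# ILS null
# ---------------------------------------------------------------------------

@dataclass
class ILSPatternProbability:
    """Estimated per-site probability that a single-mutation gene matches
    the focal-group pattern, with missingness weighting.

    ``conditional=True`` (the calibrated default) conditions on the
    simulated site being *testable*: after collapsing each species'
    chromosomes (a split species is missing, as it would be in a
    fixed-nucleotide consensus), the site must show both states among
    the non-ignored species. That is the event a tested variable
    amino-acid site represents, so it is the correct per-trial
    probability for a Binomial(N_var, p) null. ``conditional=False``
    reports the raw per-simulated-gene probability instead.
    """

    p_hat: float
    se: float
    n_sims: int
    per_config_rates: Dict[frozenset, float]
    config_freqs: Dict[frozenset, float]
    conditional: bool = True
    weights: Optional[np.ndarray] = field(default=None, repr=False)


def estimate_ils_pattern_probability(
    species_tree: SpeciesTreeCU,
    group: GroupSpec,
    missing_config_freqs: Optional[Mapping[frozenset, float]] = None,
    n_sims: int = 1_000_000,
    polarity: Optional[str] = None,
    seed: int = 0,
    chromosomes_per_species: int = 2,
    strict: bool = False,
    patterns: Optional[np.ndarray] = None,
    conditional: bool = True,
) -> ILSPatternProbability:
    """Monte-Carlo estimate of the null per-site pattern probability.

    ``missing_config_freqs`` maps frozensets of missing taxa to their
    frequencies among tested codons; the overall probability is the
    frequency-weighted mean of the per-configuration match
    probabilities. With no table given, the no-missingness pattern is
    used alone. A configuration in which a required species is missing
    can never be counted as a shared substitution, so it contributes
    probability zero; ``strict=True`` raises instead.

    With ``conditional=True`` each per-configuration probability is
    Pr[match | the simulated site is a testable variable site for that
    configuration] — every non-ignored species fixed for one state,
    both states present. This matches the sampling unit of the observed
    count (one tested variable amino-acid site), making the estimate
    directly usable as the Binomial(N_var, p) success probability.
    ``conditional=False`` gives the raw per-simulated-gene probability.
    """
    polarity = polarity or group.polarity
    if missing_config_freqs is None:
        missing_config_freqs = {frozenset(): 1.0}
    total = sum(missing_config_freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"missingness frequencies sum to {total}, expected 1")
    zero_configs = []
    for cfg in missing_config_freqs:
        if set(cfg) & set(group.required_present):
            if strict:
                raise ValueError(
                    "missingness configuration ignores required species "
                    f"{sorted(set(cfg) & set(group.required_present))}"
                )
            zero_configs.append(cfg)

    sim = MSCSimulator(species_tree, sample=chromosomes_per_species)
    if patterns is not None:
        # reuse a precomputed batch of simulated single-change genes
        # (e.g. shared across many observed datasets under one null)
        masks = np.asarray(patterns, dtype=np.uint64)
        n_sims = masks.size
    else:
        masks = sim.site_pattern_masks(n_sims, seed)
    full = np.uint64(sim.full_mask)
    group_mask = np.uint64(sim.species_mask(sorted(group.focal)))
    species = sorted(set(sim.chrom_species))
    # per-species fixation status across all simulated patterns
    der: Dict[str, np.ndarray] = {}
    anc: Dict[str, np.ndarray] = {}
    for sp in species:
        m = np.uint64(sim.species_mask([sp]))
        d = masks & m
        der[sp] = d == m
        anc[sp] = d == np.uint64(0)

    per_config: Dict[frozenset, float] = {}
    freqs: Dict[frozenset, float] = dict(missing_config_freqs)
    p_hat = 0.0
    var_acc = 0.0
    weights = np.zeros(n_sims) if not conditional else None
    for cfg, freq in missing_config_freqs.items():
        if cfg in zero_configs:
            per_config[cfg] = 0.0
            continue
        rest = [sp for sp in species if sp not in cfg]
        nonfocal = [sp for sp in rest if sp not in group.focal]
        if not nonfocal:
            raise ValueError("configuration leaves no non-focal species")
        if conditional:
            fixed = np.ones(n_sims, dtype=bool)
            any_der = np.zeros(n_sims, dtype=bool)
            any_anc = np.zeros(n_sims, dtype=bool)
            for sp in rest:
                fixed &= der[sp] | anc[sp]
                any_der |= der[sp]
                any_anc |= anc[sp]
            valid = fixed & any_der & any_anc
            match_der = np.ones(n_sims, dtype=bool)
            for sp in group.focal:
                match_der &= der[sp]
            match_anc = np.ones(n_sims, dtype=bool)
            for sp in group.focal:
                match_anc &= anc[sp]
            for sp in nonfocal:
                match_der &= anc[sp]
                match_anc &= der[sp]
            match = match_der | match_anc if polarity == "either" else match_der
            match &= valid
            n_valid = int(valid.sum())
            rate = float(match.sum() / n_valid) if n_valid else 0.0
            per_config[cfg] = rate
            p_hat += freq * rate
            var_acc += freq**2 * rate * (1 - rate) / max(n_valid, 1)
        else:
            ignored = (
                np.uint64(sim.species_mask(sorted(cfg))) if cfg else np.uint64(0)
            )
            rest_mask = full & ~ignored
            g = group_mask & rest_mask
            ng = rest_mask & ~group_mask
            d = masks & rest_mask
            match = d == g
            if polarity == "either":
                match |= d == ng
            per_config[cfg] = float(match.mean())
            weights += freq * match
    if conditional:
        se = math.sqrt(var_acc)
    else:
        p_hat = float(weights.mean())
        se = (
            float(weights.std(ddof=1) / math.sqrt(n_sims))
            if n_sims > 1
            else float("nan")
        )
    return ILSPatternProbability(
        float(p_hat), float(se), n_sims, per_config, freqs, conditional, weights
    )


@dataclass
class PhyloGWASResult:
    p_hat: float
    p_hat_se: float
    n_sims: int
    n_var: int
    observed: int
    p_value: float
    method: str


def phylogwas_pvalue(
    observed: int,
    n_var: int,
    null: Union[float, ILSPatternProbability],
    method: str = "binomial-tail",
    n_datasets: int = 1000,
    seed: int = 0,
) -> PhyloGWASResult:
    """Excess P value for the observed shared-substitution count.

    ``dataset-grouping`` partitions the simulated single-change genes
    into datasets of ``n_var`` draws and reports the fraction with at
    least the observed count; ``binomial-tail`` is the equivalent
    Binomial(n_var, p_hat) upper tail.
    """
    if n_var <= 0:
        raise ValueError("n_var must be positive")
    if observed < 0 or observed > n_var:
        raise ValueError("observed count must lie in [0, n_var]")
    if isinstance(null, ILSPatternProbability):
        p_hat, se, n_sims = null.p_hat, null.se, null.n_sims
    else:
        p_hat, se, n_sims = float(null), float("nan"), 0
    if method == "binomial-tail":
        p = float(stats.binom.sf(observed - 1, n_var, p_hat))
    elif method == "dataset-grouping":
        if not isinstance(null, ILSPatternProbability):
            raise ValueError(
                "dataset-grouping needs the simulated pattern stream "
                "(an ILSPatternProbability)"
            )
        rng = np.random.default_rng(seed)
        need = n_datasets * n_var
        if null.weights is not None:
            # fractional weights (missingness-averaged indicators) are
            # realized as Bernoulli draws so each simulated gene
            # contributes 0 or 1 exactly once per dataset assignment
            w = null.weights
            x = (rng.random(w.size) < w).astype(np.int64)
            if need <= x.size:
                x = x[:need]
            else:
                x = x[rng.integers(0, x.size, size=need)]
        else:
            # conditional null: each tested site draws a missingness
            # configuration, then a testable simulated site for it
            cfgs = list(null.config_freqs)
            probs = np.array([null.config_freqs[c] for c in cfgs])
            probs = probs / probs.sum()
            rates = np.array([null.per_config_rates[c] for c in cfgs])
            idx = rng.choice(len(cfgs), size=need, p=probs)
            x = (rng.random(need) < rates[idx]).astype(np.int64)
        counts = x.reshape(n_datasets, n_var).sum(axis=1)
        p = float((counts >= observed).mean())
    else:
        raise ValueError("method must be 'binomial-tail' or 'dataset-grouping'")
    return PhyloGWASResult(p_hat, se, n_sims, n_var, observed, p, method)
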