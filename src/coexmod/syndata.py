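"""Synthetic expression compendia, GO annotations and genomes with planted structure.

The generator emulates the statistical features of a public microarray
compendium that the downstream network analysis relies on:

* blocks of co-expressed genes driven by shared latent factors (planted
  modules),
* groups of near-duplicate (redundant) samples, as arise when related
  hybridizations are deposited many times,
* per-tissue mean shifts of module genes,
* GO annotations in which planted modules are enriched for specific terms,
* promoter sequences carrying a planted consensus motif at elevated
  frequency in one module's genes.

Everything is deterministic for a fixed :class:`SynConfig.seed`; the three
generators draw from independent named substreams so that, e.g., the genome
is identical whether or not the expression matrix was generated first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SynConfigError",
    "ModuleSpec",
    "TissueSpec",
    "GoTermSpec",
    "MotifSpec",
    "SynConfig",
    "GenomeSim",
    "simulate_expression",
    "simulate_annotation",
    "simulate_genome",
]

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# substream ids so toggling one generator never perturbs another
_STREAMS = {"expression": 1, "annotation": 2, "genome": 3}


class SynConfigError(ValueError):
    """Invalid synthetic-data configuration; the message names the field."""


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    Genes of the module load on a shared latent factor with loadings drawn
    from Uniform(0.7, 1.0) (times a per-module random sign), so planted
    pairwise correlations stay above typical network cutoffs.
    """

    size: int
    factor_sd: float = 1.0
    noise_sd: float = 0.4


@dataclass(frozen=True)
class TissueSpec:
    """A tissue block of samples with per-module mean shifts.

    ``shifts[m]`` is added to every module-``m`` gene in this tissue's
    samples, creating the tissue-driven component of co-expression.
    """

    name: str
    n_samples: int
    shifts: tuple[float, ...] = ()


@dataclass(frozen=True)
class GoTermSpec:
    accession: str
    name: str
    background_rate: float
    planted_module: int | None = None
    planted_rate: float = 0.0


@dataclass(frozen=True)
class MotifSpec:
    consensus: str
    planted_module: int
    insertion_rate: float = 0.8
    mutation_prob: float = 0.05


def _default_modules() -> tuple[ModuleSpec, ...]:
    return tuple(ModuleSpec(size=50) for _ in range(3))


def _default_tissues() -> tuple[TissueSpec, ...]:
    # centered, near-orthogonal per-module tissue profiles: module 0 is
    # xylem-specific, module 1 leaf-biased, module 2 root-biased
    return (
        TissueSpec("young_leaf", 30, (-0.5, 1.2, -0.4)),
        TissueSpec("mature_leaf", 30, (-0.5, 0.4, -0.4)),
        TissueSpec("root", 30, (-0.5, -0.8, 1.2)),
        TissueSpec("xylem", 30, (1.5, -0.8, -0.4)),
    )


def _default_go_terms() -> tuple[GoTermSpec, ...]:
    return (
        GoTermSpec("GO:0009834", "plant-type secondary cell wall biogenesis", 0.02, 0, 0.8),
        GoTermSpec("GO:0009833", "plant-type primary cell wall biogenesis", 0.02, 1, 0.8),
        GoTermSpec("GO:0006073", "cellular glucan metabolic process", 0.02, 2, 0.8),
        GoTermSpec("GO:0006412", "translation", 0.10),
        GoTermSpec("GO:0006355", "regulation of transcription", 0.12),
        GoTermSpec("GO:0055114", "oxidation-reduction process", 0.15),
        GoTermSpec("GO:0009058", "biosynthetic process", 0.25),
        GoTermSpec("GO:0006950", "response to stress", 0.08),
        GoTermSpec("GO:0007049", "cell cycle", 0.05),
    )


@dataclass(frozen=True)
class SynConfig:
    """Configuration of the synthetic compendium.

    Defaults describe the standard study conditions used throughout the test
    suite: 2,000 genes, 120 samples in four tissue blocks, three planted
    modules of 50 genes, five groups of four near-duplicate samples, one
    planted promoter motif and three planted GO terms.
    """

    n_genes: int = 2000
    n_samples: int = 120
    modules: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    n_redundant_groups: int = 5
    redundancy_size: int = 4
    tissues: tuple[TissueSpec, ...] = field(default_factory=_default_tissues)
    go_terms: tuple[GoTermSpec, ...] = field(default_factory=_default_go_terms)
    motif: MotifSpec | None = field(default_factory=lambda: MotifSpec("ACCCCC", 0))
    promoter_len: int = 2000
    background_sd: float = 1.0
    baseline: float = 8.0  # RMA-like log2-intensity offset; keeps signals positive
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def bad(fieldname: str, why: str) -> SynConfigError:
            return SynConfigError(f"SynConfig.{fieldname}: {why}")

        if self.n_genes < 1:
            raise bad("n_genes", "must be >= 1")
        if self.n_samples < 1:
            raise bad("n_samples", "must be >= 1")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise bad("modules", "sum of module sizes exceeds n_genes")
        for i, m in enumerate(self.modules):
            if m.size < 1:
                raise bad("modules", f"module {i} size must be >= 1")
            if m.factor_sd < 0 or m.noise_sd < 0:
                raise bad("modules", f"module {i} sds must be >= 0")
        if self.tissues:
            if sum(t.n_samples for t in self.tissues) != self.n_samples:
                raise bad("tissues", "tissue sample counts must sum to n_samples")
            for t in self.tissues:
                if t.shifts and len(t.shifts) != len(self.modules):
                    raise bad("tissues", f"tissue {t.name!r} needs one shift per module")
        if self.n_redundant_groups < 0 or self.redundancy_size < 0:
            raise bad("n_redundant_groups", "counts must be >= 0")
        if self.n_redundant_groups > 0 and self.redundancy_size > 1:
            if self.n_redundant_groups * self.redundancy_size > self.n_samples:
                raise bad("n_redundant_groups", "redundant samples exceed n_samples")
        for t in self.go_terms:
            if not 0.0 <= t.background_rate <= 1.0 or not 0.0 <= t.planted_rate <= 1.0:
                raise bad("go_terms", f"{t.accession}: rates must be in [0, 1]")
            if t.planted_module is not None and not 0 <= t.planted_module < len(self.modules):
                raise bad("go_terms", f"{t.accession}: planted_module out of range")
        if self.motif is not None:
            m = self.motif
            if len(m.consensus) not in (6, 8):
                raise bad("motif", "consensus length must be 6 or 8")
            if set(m.consensus) - set("ACGT"):
                raise bad("motif", "consensus must be over {A,C,G,T}")
            if not 0 <= m.planted_module < len(self.modules):
                raise bad("motif", "planted_module out of range")
            if not 0.0 <= m.insertion_rate <= 1.0 or not 0.0 <= m.mutation_prob <= 1.0:
                raise bad("motif", "rates must be in [0, 1]")
        if self.promoter_len < 1:
            raise bad("promoter_len", "must be >= 1")
        if self.background_sd < 0:
            raise bad("background_sd", "must be >= 0")

    # -- derived layout ----------------------------------------------------

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(1, self.n_samples + 1)]

    def module_labels(self) -> pd.Series:
        """Planted module of each gene (-1 for background), indexed by gene id."""
        labels = np.full(self.n_genes, -1, dtype=int)
        start = 0
        for m, spec in enumerate(self.modules):
            labels[start : start + spec.size] = m
            start += spec.size
        return pd.Series(labels, index=self.gene_ids(), name="module")

    def tissue_of_sample(self) -> pd.Series:
        """Tissue name of each sample, indexed by sample id."""
        names: list[str] = []
        for t in self.tissues:
            names.extend([t.name] * t.n_samples)
        if not names:
            names = ["all"] * self.n_samples
        return pd.Series(names, index=self.sample_ids(), name="tissue")

    def redundant_groups(self) -> list[list[int]]:
        """Column indices of each redundant group; element 0 is the base sample."""
        if self.n_redundant_groups == 0 or self.redundancy_size < 2:
            return []
        stride = self.n_samples // self.n_redundant_groups
        return [
            list(range(g * stride, g * stride + self.redundancy_size))
            for g in range(self.n_redundant_groups)
        ]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


def with_seed(cfg: SynConfig, seed: int) -> SynConfig:
    """Copy of ``cfg`` with a different seed."""
    return dataclasses.replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(cfg: SynConfig) -> pd.DataFrame:
    """Genes x samples expression matrix with planted module structure.

    Module genes follow ``x_gs = lambda_g * f_ms + eps_gs`` with a shared
    per-module factor ``f_ms ~ N(0, factor_sd)``, loadings
    ``lambda_g ~ U(0.7, 1.0)`` carrying a random per-module sign, and noise
    ``eps ~ N(0, noise_sd)``; background genes are independent
    ``N(0, background_sd)`` noise.  Redundant-sample copies add
    ``N(0, 0.05 * background_sd)`` jitter to their base column, and per-tissue
    mean shifts are added to module genes.  A constant ``baseline`` shifts the
    whole matrix onto a positive intensity-like scale.
    """
    rng = cfg.rng("expression")
    g, s = cfg.n_genes, cfg.n_samples
    x = rng.normal(0.0, cfg.background_sd, size=(g, s))

    labels = cfg.module_labels().to_numpy()
    start = 0
    for m, spec in enumerate(cfg.modules):
        rows = slice(start, start + spec.size)
        start += spec.size
        factor = rng.normal(0.0, spec.factor_sd, size=s)
        sign = rng.choice([-1.0, 1.0])
        loadings = sign * rng.uniform(0.7, 1.0, size=spec.size)
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.size, s))
        x[rows] = loadings[:, None] * factor[None, :] + noise

    # per-tissue mean shifts for module genes
    col = 0
    for t in cfg.tissues:
        cols = slice(col, col + t.n_samples)
        col += t.n_samples
        if not t.shifts:
            continue
        for m in range(len(cfg.modules)):
            x[labels == m, cols] += t.shifts[m]

    # redundant groups: copies of a base column plus small jitter
    for group in cfg.redundant_groups():
        base = group[0]
        for copy in group[1:]:
            x[:, copy] = x[:, base] + rng.normal(0.0, 0.05 * cfg.background_sd, size=g)

    x += cfg.baseline
    return pd.DataFrame(x, index=cfg.gene_ids(), columns=cfg.sample_ids())


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(cfg: SynConfig, genes: list[str] | None = None) -> pd.DataFrame:
    """Gene/term annotation table with terms enriched in their planted modules.

    Each gene receives term ``t`` with probability ``background_rate``, raised
    to ``planted_rate`` for genes of the term's planted module.  Returns a
    tidy frame with columns ``gene_id``, ``term_accession``, ``term_name``.
    """
    if genes is None:
        genes = cfg.gene_ids()
    expected = cfg.gene_ids()
    if list(genes) != expected:
        raise SynConfigError("SynConfig/genes: gene list does not match this configuration")
    rng = cfg.rng("annotation")
    labels = cfg.module_labels().to_numpy()
    rows: list[tuple[str, str, str]] = []
    for term in cfg.go_terms:
        p = np.full(cfg.n_genes, term.background_rate)
        if term.planted_module is not None:
            p[labels == term.planted_module] = term.planted_rate
        hit = rng.random(cfg.n_genes) < p
        rows.extend((genes[i], term.accession, term.name) for i in np.flatnonzero(hit))
    return pd.DataFrame(rows, columns=["gene_id", "term_accession", "term_name"])


# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeSim:
    """In-memory synthetic genome: one contig per gene plus gene models.

    ``features`` uses GFF3 conventions (1-based inclusive ``start``/``end``).
    ``motif_truth`` records where the consensus was planted (0-based offset
    within the biological promoter, 5'->3' toward the gene).
    """

    contigs: dict[str, str]
    features: pd.DataFrame  # seqid, source, type, start, end, score, strand, frame, attributes
    promoters: pd.DataFrame  # gene_id, seqid, strand, promoter (truth, pre-extraction)
    motif_truth: pd.DataFrame  # gene_id, offset, inserted


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_genome(cfg: SynConfig, genes: list[str] | None = None,
                    cds_len: int = 300, flank: int = 25) -> GenomeSim:
    """Synthetic genome FASTA/GFF3 content with planted promoter motifs.

    Each gene gets its own contig holding ``flank`` random bases, the
    ``promoter_len`` promoter, a CDS of ``cds_len`` bases and a trailing
    flank; the whole construct is reverse-complemented for genes assigned to
    the minus strand (strand chosen at random per gene).  For genes of the
    motif's planted module the consensus is written into the promoter at a
    uniform-random offset with probability ``insertion_rate``, each base
    flipped to a random other base with probability ``mutation_prob``.
    """
    if genes is None:
        genes = cfg.gene_ids()
    if list(genes) != cfg.gene_ids():
        raise SynConfigError("SynConfig/genes: gene list does not match this configuration")
    rng = cfg.rng("genome")
    labels = cfg.module_labels().to_numpy()
    motif = cfg.motif

    contigs: dict[str, str] = {}
    feat_rows = []
    prom_rows = []
    truth_rows = []
    L = cfg.promoter_len
    for i, gene in enumerate(genes):
        n_total = flank + L + cds_len + flank
        arr = rng.integers(0, 4, size=n_total)
        prom = arr[flank : flank + L]
        if (
            motif is not None
            and labels[i] == motif.planted_module
            and L >= len(motif.consensus)
            and rng.random() < motif.insertion_rate
        ):
            k = len(motif.consensus)
            pos = int(rng.integers(0, L - k + 1))
            ins = np.array([_BASES.tolist().index(b) for b in motif.consensus])
            for j in range(k):
                if rng.random() < motif.mutation_prob:
                    ins[j] = (ins[j] + rng.integers(1, 4)) % 4
            prom[pos : pos + k] = ins
            truth_rows.append((gene, pos, "".join(_BASES[ins])))
        seq = "".join(_BASES[arr])
        strand = "+" if rng.random() < 0.5 else "-"
        seqid = f"ctg_{gene}"
        if strand == "+":
            cds_start = flank + L + 1  # 1-based
            cds_end = cds_start + cds_len - 1
        else:
            seq = reverse_complement(seq)
            cds_start = flank + 1
            cds_end = flank + cds_len
        contigs[seqid] = seq
        feat_rows.append((seqid, "coexmod_syndata", "gene", 1, n_total, ".", strand, ".",
                          f"ID={gene}"))
        feat_rows.append((seqid, "coexmod_syndata", "CDS", cds_start, cds_end, ".", strand, "0",
                          f"ID=cds_{gene};Parent={gene}"))
        prom_rows.append((gene, seqid, strand, "".join(_BASES[prom])))

    features = pd.DataFrame(
        feat_rows,
        columns=["seqid", "source", "type", "start", "end", "score", "strand", "frame",
                 "attributes"],
    )
    promoters = pd.DataFrame(prom_rows, columns=["gene_id", "seqid", "strand", "promoter"])
    motif_truth = pd.DataFrame(truth_rows, columns=["gene_id", "offset", "inserted"])
    return GenomeSim(contigs, features, promoters, motif_truth)
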