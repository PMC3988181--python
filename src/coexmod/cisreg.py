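"""Promoter extraction and degenerate k-mer overrepresentation.

The promoter of a gene is the stretch of (by default) 2,000 bases upstream
of its translation start, strand-corrected so the sequence reads 5'->3'
toward the gene.  Motif discovery enumerates all ``4^k`` candidate k-mers
(k = 6 or 8, the "small" motif-search convention) and counts
mismatch-tolerant occurrences — Hamming distance at most 1 for 6-mers and at
most 2 for 8-mers — in a foreground promoter set (a module) and a background
set.  A candidate is overrepresented when the upper-tail binomial
probability of its foreground count, at the background per-window rate,
falls below ``alpha``; survivors are ranked by log-odds of the foreground
versus background rates.  Discovered motifs are finally matched against a
catalog of known cis-regulatory elements given as IUPAC consensus strings.

Mismatch-tolerant counts for all candidates at once are obtained from the
exact k-mer spectrum by Hamming-ball summation over position marginals,
which keeps the full 6-mer and 8-mer enumerations fast.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data.IUPACData import ambiguous_dna_values

from . import io as cio
from .syndata import reverse_complement

__all__ = [
    "MotifResult",
    "extract_promoters",
    "count_kmer",
    "discover_motifs",
    "match_catalog",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_N_CODE = 4
_ALLOWED_MM = {6: 1, 8: 2}


@dataclass
class MotifResult:
    """One overrepresented k-mer and its enrichment statistics."""

    motif: str
    fg_count: int
    fg_seqs_with_hit: int
    bg_rate: float
    log_odds: float
    p_enrich: float
    matches: list[tuple[str, int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# promoter extraction


def _load_features(models) -> pd.DataFrame:
    if isinstance(models, pd.DataFrame):
        return models
    import gffutils

    db = gffutils.create_db(
        str(models), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        attrs = ";".join(f"{k}={v[0]}" for k, v in feat.attributes.items())
        rows.append((feat.seqid, feat.source, feat.featuretype, feat.start, feat.end,
                     feat.score or ".", feat.strand, feat.frame or ".", attrs))
    return pd.DataFrame(rows, columns=cio.GFF3_COLUMNS)


def _attr_value(attributes: str, key: str) -> str | None:
    for part in attributes.split(";"):
        if part.startswith(f"{key}="):
            return part.split("=", 1)[1]
    return None


def extract_promoters(
    genome, models, genes: list[str], length: int = 2000
) -> tuple[dict[str, str], list[str]]:
    """Strand-corrected upstream regions from the translation start site.

    ``genome`` is a FASTA path or a contig-name -> sequence dict; ``models``
    a GFF3 path or an equivalent 9-column frame.  For a plus-strand gene the
    promoter is the ``length`` bases ending immediately before the CDS start
    (1-based GFF coordinates); for a minus-strand gene, the reverse
    complement of the bases immediately after the CDS end.  Promoters
    truncated at a contig boundary are returned shorter, with a warning.
    Returns ``(promoters, skipped)`` where ``skipped`` lists genes without a
    CDS record.
    """
    contigs = genome if isinstance(genome, dict) else cio.read_fasta(genome)
    feats = _load_features(models)
    cds = feats[feats["type"] == "CDS"].copy()
    cds["gene_id"] = cds["attributes"].map(
        lambda a: _attr_value(a, "Parent") or _attr_value(a, "ID")
    )
    grouped = cds.groupby("gene_id")

    promoters: dict[str, str] = {}
    skipped: list[str] = []
    truncated: list[str] = []
    for gene in genes:
        if gene not in grouped.groups:
            skipped.append(gene)
            continue
        rows = grouped.get_group(gene)
        seqid = rows["seqid"].iloc[0]
        strand = rows["strand"].iloc[0]
        seq = contigs[seqid]
        if strand == "+":
            start = int(rows["start"].min())  # 1-based CDS start
            lo = max(1, start - length)
            prom = seq[lo - 1 : start - 1]
        else:
            end = int(rows["end"].max())
            hi = min(len(seq), end + length)
            prom = reverse_complement(seq[end:hi])
        if len(prom) < length:
            truncated.append(gene)
        promoters[gene] = prom.upper()
    if truncated:
        warnings.warn(
            f"{len(truncated)} promoter(s) truncated at contig boundaries", stacklevel=2
        )
    if skipped:
        warnings.warn(f"{len(skipped)} gene(s) without CDS records skipped", stacklevel=2)
    return promoters, skipped


# ---------------------------------------------------------------------------
# k-mer counting


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, _N_CODE, dtype=np.int64)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def _motif_vector(motif: str) -> np.ndarray:
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if len(motif) not in _ALLOWED_MM:
        raise ValueError("motif length must be 6 or 8")
    return np.array([_BASE_INDEX[b] for b in motif], dtype=np.int64)


def count_kmer(
    promoters: dict[str, str], motif: str, max_mm: int, both_strands: bool = False
) -> tuple[int, int]:
    """Mismatch-tolerant occurrence counts of one motif.

    Sliding-window Hamming count: every window within ``max_mm`` mismatches
    counts (overlapping occurrences included); windows containing ``N``
    never match.  Returns ``(total occurrences, sequences with >= 1)``.
    With ``both_strands`` the reverse complement of the motif is scanned as
    well and per-strand occurrences add up.
    """
    vec = _motif_vector(motif)
    queries = [vec]
    if both_strands:
        queries.append(_motif_vector(reverse_complement(motif)))
    k = len(vec)
    total = 0
    n_seqs = 0
    for seq in promoters.values():
        enc = _encode(seq)
        if len(enc) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = ~(windows == _N_CODE).any(axis=1)
        hits = 0
        for q in queries:
            mm = (windows != q).sum(axis=1)
            hits += int((valid & (mm <= max_mm)).sum())
        total += hits
        n_seqs += hits > 0
    return total, n_seqs


def _spectrum(promoters: dict[str, str], k: int) -> tuple[np.ndarray, int]:
    """Exact k-mer spectrum (length 4^k) and the number of valid windows."""
    mult = 4 ** np.arange(k - 1, -1, -1)
    counts = np.zeros(4**k, dtype=np.int64)
    n_windows = 0
    for seq in promoters.values():
        enc = _encode(seq)
        if len(enc) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = ~(windows == _N_CODE).any(axis=1)
        codes = windows[valid] @ mult
        counts += np.bincount(codes, minlength=4**k)
        n_windows += int(valid.sum())
    return counts, n_windows


def _ball_counts(counts: np.ndarray, k: int, max_mm: int) -> np.ndarray:
    """Hamming-ball sums of an exact spectrum, radius ``max_mm`` (<= 2)."""
    if max_mm == 0:
        return counts.copy()
    shape = (4,) * k
    arr = counts.reshape(shape)
    flat = counts.astype(np.int64)
    marg1 = {}
    total = flat.copy()
    for p in range(k):
        tp = np.broadcast_to(arr.sum(axis=p, keepdims=True), shape).reshape(-1)
        marg1[p] = tp
        total += tp - flat  # exactly one mismatch at position p
    if max_mm >= 2:
        for p, q in itertools.combinations(range(k), 2):
            tpq = np.broadcast_to(arr.sum(axis=(p, q), keepdims=True), shape).reshape(-1)
            total += tpq - marg1[p] - marg1[q] + flat  # exactly two mismatches at p, q
    return total


def _code_to_motif(code: int, k: int) -> str:
    bases = "ACGT"
    out = []
    for _ in range(k):
        out.append(bases[code % 4])
        code //= 4
    return "".join(reversed(out))


def discover_motifs(
    fg: dict[str, str],
    bg: dict[str, str],
    k: int,
    alpha: float = 0.05,
    top: int = 10,
    max_mm: int | None = None,
    both_strands: bool = False,
) -> list[MotifResult]:
    """Exhaustively score all 4^k candidate motifs for overrepresentation.

    ``p_enrich`` is the upper-tail binomial probability of at least the
    observed foreground count over the foreground windows at the background
    per-window rate; motifs with ``p_enrich < alpha`` are ranked by
    ``log2((fg rate)/max(bg rate, pseudo))`` with ``pseudo = 0.5/bg
    windows`` and truncated to ``top``.
    """
    if not fg or not bg:
        raise ValueError("foreground and background promoter sets must be non-empty")
    if set(fg) & set(bg):
        raise ValueError("foreground and background gene sets overlap")
    if k not in _ALLOWED_MM:
        raise ValueError("k must be 6 or 8")
    if max_mm is None:
        max_mm = _ALLOWED_MM[k]

    fg_exact, fg_windows = _spectrum(fg, k)
    bg_exact, bg_windows = _spectrum(bg, k)
    if fg_windows == 0 or bg_windows == 0:
        raise ValueError("no scannable windows in foreground or background")
    fg_counts = _ball_counts(fg_exact, k, max_mm)
    bg_counts = _ball_counts(bg_exact, k, max_mm)
    if both_strands:
        rc = _rc_permutation(k)
        fg_counts = fg_counts + fg_counts[rc]
        bg_counts = bg_counts + bg_counts[rc]

    bg_rate = bg_counts / bg_windows
    pseudo = 0.5 / bg_windows
    p = stats.binom.sf(fg_counts - 1, fg_windows, np.clip(bg_rate, 0.0, 1.0))
    with np.errstate(divide="ignore"):
        log_odds = np.log2(
            np.maximum(fg_counts, 0) / fg_windows / np.maximum(bg_rate, pseudo)
        )
    log_odds = np.where(fg_counts > 0, log_odds, -np.inf)

    keep = np.flatnonzero(p < alpha)
    order = keep[np.lexsort((keep, -log_odds[keep]))][: max(top, 0)]
    results = []
    for code in order:
        motif = _code_to_motif(int(code), k)
        _total, n_seq = count_kmer(fg, motif, max_mm, both_strands)
        results.append(
            MotifResult(
                motif=motif,
                fg_count=int(fg_counts[code]),
                fg_seqs_with_hit=int(n_seq),
                bg_rate=float(bg_rate[code]),
                log_odds=float(log_odds[code]),
                p_enrich=float(p[code]),
            )
        )
    return results


def _rc_permutation(k: int) -> np.ndarray:
    codes = np.arange(4**k)
    digits = np.empty((4**k, k), dtype=np.int64)
    c = codes.copy()
    for pos in range(k - 1, -1, -1):
        digits[:, pos] = c % 4
        c //= 4
    rc_digits = 3 - digits[:, ::-1]
    mult = 4 ** np.arange(k - 1, -1, -1)
    return rc_digits @ mult


# ---------------------------------------------------------------------------
# catalog matching


def _iupac_classes(consensus: str, accession: str) -> list[set[str]]:
    classes = []
    for ch in consensus.upper():
        try:
            classes.append(set(ambiguous_dna_values[ch]))
        except KeyError:
            raise ValueError(
                f"catalog entry {accession}: invalid IUPAC code {ch!r} in consensus"
            ) from None
    return classes


def _best_alignment_mm(motif: str, classes: list[set[str]]) -> int | None:
    """Fewest out-of-class positions over ungapped containments, or None."""
    lm, lc = len(motif), len(classes)
    best = None
    if lm <= lc:
        for off in range(lc - lm + 1):
            mm = sum(motif[i] not in classes[off + i] for i in range(lm))
            best = mm if best is None else min(best, mm)
    else:
        for off in range(lm - lc + 1):
            mm = sum(motif[off + j] not in classes[j] for j in range(lc))
            best = mm if best is None else min(best, mm)
    return best


def match_catalog(
    results: list[MotifResult], catalog: pd.DataFrame, reverse_complement_too: bool = True
) -> list[MotifResult]:
    """Annotate discovered motifs with matching known-CRE catalog entries.

    An entry matches when some ungapped alignment — the motif fully inside
    the consensus, or the consensus fully inside the motif — leaves at most
    1 (6-mers) or 2 (8-mers) motif positions outside the IUPAC class of the
    aligned consensus position.  Matches are stored on each result, sorted
    by mismatch count; by default the motif's reverse complement is tried as
    well (cis-elements are double-stranded).
    """
    if catalog.empty:
        raise ValueError("catalog is empty")
    entries = [
        (row.accession, _iupac_classes(row.consensus, row.accession), row.description)
        for row in catalog.itertuples(index=False)
    ]
    for res in results:
        allowance = _ALLOWED_MM[len(res.motif)]
        variants = [res.motif]
        if reverse_complement_too:
            variants.append(reverse_complement(res.motif))
        matches = []
        for accession, classes, description in entries:
            mms = [m for m in (_best_alignment_mm(v, classes) for v in variants)
                   if m is not None]
            if mms and min(mms) <= allowance:
                matches.append((accession, min(mms), description))
        res.matches = sorted(matches, key=lambda t: (t[1], t[0]))
    return results


def results_to_frame(results: list[MotifResult], module_id=None) -> pd.DataFrame:
    """Flatten motif results (best catalog match per motif) for TSV export."""
    rows = []
    for rank, res in enumerate(results, start=1):
        accession, mm, desc = (res.matches[0] if res.matches else ("", "", ""))
        rows.append((module_id, rank, res.motif, res.p_enrich, res.fg_count,
                     res.fg_seqs_with_hit, round(res.log_odds, 4), accession, mm, desc))
    return pd.DataFrame(
        rows,
        columns=["module", "rank", "motif", "p_enrich", "fg_count", "fg_seqs_with_hit",
                 "log_odds", "accession", "mismatches", "description"],
    )


def load_default_catalog() -> pd.DataFrame:
    """Packaged known-CRE catalog (synthetic stand-in, PLACE-style layout)."""
    path = Path(__file__).parent / "data" / "cre_catalog_synthetic.tsv"
    return cio.read_catalog(path)
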