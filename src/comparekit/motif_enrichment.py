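"""Promoter extraction, PWM scanning and motif enrichment ranking.

For a gene list, promoter windows upstream of the TSS are pulled from a
genome FASTA (strand-aware, up to 50 kb as in standard promoter screens).
Each PWM is scored on each promoter by its best log2-odds hit over both
strands; the enrichment statistic per motif is

    T = mean over promoters of the best-hit score,

compared against a null built by dinucleotide-shuffling every promoter
(Altschul-Erickson Euler-path shuffle, preserving dinucleotide counts)
``n_shuffles`` times: z = (mu0 - T) / sigma0 with the convention that
*negative z means enriched*, and p the one-sided normal tail.  This
statistic is an openly specified stand-in for proprietary/undocumented
region-based motif rankers; its absolute values are not comparable to any
particular external tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PWM, FormatError, GenomicInterval, ValidationError, write_bed

log = logging.getLogger("comparekit")

MAX_WINDOW_BP = 50_000

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ScanHit(NamedTuple):
    score: float
    position: int
    strand: str


@dataclass
class PromoterSet:
    """Strand-aware promoter sequences: (gene id, interval, sequence)."""

    records: list[tuple[str, GenomicInterval, str]]
    window: int

    def __post_init__(self) -> None:
        for gene, interval, seq in self.records:
            if len(seq) != len(interval):
                raise ValidationError(
                    f"{gene}: sequence length {len(seq)} != interval length "
                    f"{len(interval)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [seq for _, _, seq in self.records]

    def intervals(self) -> list[GenomicInterval]:
        return [iv for _, iv, _ in self.records]


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    z: float  # negative = enriched
    p: float
    neg_log10_p: float
    rank: int
    t_observed: float
    null_mean: float
    null_sd: float

    @property
    def neg_log10_p_x10(self) -> float:
        """-log10 p scaled x10 (the scale some motif rankers print)."""
        return 10.0 * self.neg_log10_p


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------

def _load_annotation(annotation) -> pd.DataFrame:
    if isinstance(annotation, (str, Path)):
        annotation = pd.read_csv(annotation, sep="\t")
    cols = {c.lower(): c for c in annotation.columns}
    needed = ["gene", "chrom", "tss", "strand"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise FormatError(f"annotation lacks column(s) {missing}")
    frame = annotation.rename(columns={cols[c]: c for c in needed})
    return frame.set_index(frame["gene"].astype(str))


def _genome_accessor(genome):
    if isinstance(genome, Mapping):
        contigs = {k: str(v).upper() for k, v in genome.items()}
        return contigs.keys().__contains__, \
            lambda c: len(contigs[c]), \
            lambda c, s, e: contigs[c][s:e]
    from pyfaidx import Fasta
    fa = Fasta(str(genome))
    return fa.keys().__contains__, \
        lambda c: len(fa[c]), \
        lambda c, s, e: str(fa[c][s:e]).upper()


def extract_promoters(
    genes: Sequence[str],
    annotation,
    genome,
    window_bp: int = MAX_WINDOW_BP,
    bed_out: str | Path | None = None,
) -> PromoterSet:
    """Extract upstream promoter windows for a gene list.

    Plus strand: [max(0, TSS - window), TSS).  Minus strand:
    [TSS, TSS + window), reverse-complemented so all promoters read
    5'→3' toward the TSS.  Windows are truncated at contig boundaries with
    a warning.  ``annotation`` is a TSV path or DataFrame with columns
    gene/chrom/tss/strand (TSS 0-based); ``genome`` a FASTA path or an
    id -> sequence mapping.  ``bed_out`` additionally writes the intervals
    as BED6.
    """
    if not 0 < window_bp <= MAX_WINDOW_BP:
        raise ValidationError(f"window_bp must lie in 1..{MAX_WINDOW_BP}")
    ann = _load_annotation(annotation)
    absent = [g for g in genes if g not in ann.index]
    if absent:
        raise ValidationError(f"gene(s) absent from annotation: {absent}")
    has_contig, contig_len, fetch = _genome_accessor(genome)

    records: list[tuple[str, GenomicInterval, str]] = []
    for gene in genes:
        row = ann.loc[gene]
        chrom, tss, strand = str(row["chrom"]), int(row["tss"]), str(row["strand"])
        if strand not in ("+", "-"):
            raise ValidationError(f"{gene}: bad strand {strand!r}")
        if not has_contig(chrom):
            raise ValidationError(f"{gene}: contig {chrom!r} absent from genome")
        clen = contig_len(chrom)
        if strand == "+":
            start, end = tss - window_bp, tss
        else:
            start, end = tss, tss + window_bp
        if start < 0:
            log.warning(
                "%s: window truncated at contig start (wanted %d bp, got %d)",
                gene, window_bp, end,
            )
            start = 0
        if end > clen:
            log.warning(
                "%s: window truncated at contig end (wanted %d bp, got %d)",
                gene, window_bp, clen - start,
            )
            end = clen
        interval = GenomicInterval(chrom, start, end, name=gene, strand=strand)
        seq = fetch(chrom, start, end)
        if strand == "-":
            seq = reverse_complement(seq)
        records.append((gene, interval, seq))

    proms = PromoterSet(records=records, window=window_bp)
    if bed_out is not None:
        write_bed(proms.intervals(), bed_out)
    return proms


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def _log_odds(pwm: PWM) -> np.ndarray:
    """5 x L log2-odds with an all-zero row for ambiguous bases (N)."""
    lo = np.zeros((5, len(pwm)))
    lo[:4] = np.log2(pwm.matrix / pwm.background[:, None])
    return lo


def _encode(seq: str) -> np.ndarray:
    return np.fromiter(
        (_ENCODE.get(b, 4) for b in seq.upper()), dtype=np.int8, count=len(seq)
    )


def _window_scores(encoded: np.ndarray, lo: np.ndarray) -> np.ndarray:
    L = lo.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    return lo[windows, np.arange(L)].sum(axis=1)


def scan_best_score(seq: str, pwm: PWM) -> ScanHit:
    """Best log2-odds hit of a PWM over both strands of a sequence.

    Scores are summed per column of log2(P_pwm / P_background); ambiguous
    bases contribute 0 (the background expectation).  Ties go to the
    forward strand, then the leftmost offset.
    """
    L = len(pwm)
    if len(seq) < L:
        raise ValidationError(
            f"sequence length {len(seq)} shorter than motif length {L}"
        )
    lo = _log_odds(pwm)
    lo_rc = lo[[3, 2, 1, 0, 4], ::-1]  # scan forward seq with revcomp motif
    enc = _encode(seq)
    fwd = _window_scores(enc, lo)
    rev = _window_scores(enc, lo_rc)
    i_f, i_r = int(np.argmax(fwd)), int(np.argmax(rev))
    if fwd[i_f] >= rev[i_r]:
        return ScanHit(float(fwd[i_f]), i_f, "+")
    return ScanHit(float(rev[i_r]), i_r, "-")


def _best_scores_batch(encoded_seqs: list[np.ndarray], pwm: PWM) -> np.ndarray:
    lo = _log_odds(pwm)
    lo_rc = lo[[3, 2, 1, 0, 4], ::-1]
    out = np.empty(len(encoded_seqs))
    for i, enc in enumerate(encoded_seqs):
        out[i] = max(
            _window_scores(enc, lo).max(), _window_scores(enc, lo_rc).max()
        )
    return out


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Uniform random shuffle preserving exact dinucleotide counts.

    Euler-path construction: pick random "last edges" forming a tree toward
    the terminal character (rejection sampling), randomly permute the
    remaining edges per character, then walk the path.
    """
    if len(seq) < 3:
        return seq
    seq = seq.upper()
    succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, []).append(b)
    last_char = seq[-1]
    vertices = list(succ)

    # choose last edges forming a tree into last_char
    while True:
        last_edge = {
            v: succ[v][rng.integers(len(succ[v]))]
            for v in vertices if v != last_char
        }
        ok = True
        for v in last_edge:
            cur, hops = v, 0
            while cur != last_char:
                if cur not in last_edge or hops > 4:
                    ok = False
                    break
                cur = last_edge[cur]
                hops += 1
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(succ[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        perm = [edges[i] for i in rng.permutation(len(edges))]
        if v in last_edge:
            perm.append(last_edge[v])
        shuffled[v] = perm

    out = [seq[0]]
    counters = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        v = out[-1]
        out.append(shuffled[v][counters[v]])
        counters[v] += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def enrich_motifs(
    proms: PromoterSet,
    pwms: Sequence[PWM],
    n_shuffles: int = 100,
    seed: int | None = None,
) -> list[MotifEnrichmentResult]:
    """Rank motifs by enrichment of best-hit scores over a shuffled null.

    The observed statistic per motif is the mean best-hit score over
    promoters; the null distribution is that same statistic on dinucleotide-
    shuffled copies of every promoter (``n_shuffles`` independent shuffle
    replicates, shared across motifs).  z = (mu0 - T)/sigma0 (negative =
    enriched); p is the one-sided normal tail; results are sorted by
    -log10 p descending, ties broken by motif id.
    """
    if n_shuffles < 20:
        raise ValidationError(
            f"n_shuffles={n_shuffles} < 20 gives an unstable null"
        )
    if len(proms) == 0 or len(pwms) == 0:
        raise ValidationError("need at least one promoter and one PWM")
    rng = np.random.default_rng(seed)

    observed = [_encode(s) for s in proms.sequences()]
    min_len = min(len(e) for e in observed)
    max_L = max(len(p) for p in pwms)
    if min_len < max_L:
        raise ValidationError(
            f"shortest promoter ({min_len} bp) shorter than longest motif "
            f"({max_L} bp)"
        )
    # shuffle replicates are generated once and shared across motifs
    null_sets = [
        [_encode(dinucleotide_shuffle(s, rng)) for s in proms.sequences()]
        for _ in range(n_shuffles)
    ]

    results = []
    for pwm in pwms:
        t_obs = float(_best_scores_batch(observed, pwm).mean())
        t_null = np.array(
            [_best_scores_batch(null, pwm).mean() for null in null_sets]
        )
        mu0, sd0 = float(t_null.mean()), float(t_null.std(ddof=1))
        if sd0 == 0:
            log.warning("%s: degenerate null (sd 0); z set to 0", pwm.motif_id)
            z, p = 0.0, 1.0
        else:
            z = (mu0 - t_obs) / sd0
            p = float(stats.norm.cdf(z))
        p = max(p, np.nextafter(0, 1))
        results.append((pwm.motif_id, z, p, -np.log10(p), t_obs, mu0, sd0))

    results.sort(key=lambda r: (-r[3], r[0]))
    return [
        MotifEnrichmentResult(
            motif_id=m, z=float(z), p=float(p), neg_log10_p=float(nlp),
            rank=i + 1, t_observed=t, null_mean=mu, null_sd=sd,
        )
        for i, (m, z, p, nlp, t, mu, sd) in enumerate(results)
    ]


def enrichment_table(results: Sequence[MotifEnrichmentResult]) -> pd.DataFrame:
    """Tabular view with both -log10 p and the x10-scaled column."""
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in results],
            "z": [r.z for r in results],
            "neg_log10_p": [r.neg_log10_p for r in results],
            "neg_log10_p_x10": [r.neg_log10_p_x10 for r in results],
            "rank": [r.rank for r in results],
        }
    )
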