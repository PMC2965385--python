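"""K-mer enrichment landscapes over 3' UTRs ranked by decay.

Genes are ordered most-decayed first; for each of ``nbins`` growing
leading subsets (cumulative bins by gene count) and each DNA word of
length k, a hypergeometric upper-tail p-value asks whether the word's
overlapping occurrences concentrate in the leading sequences.  The
population is the total number of unambiguous k-mer windows across all
UTRs, the successes are the word's total occurrences, and the draws are
the windows contributed by the leading genes.  The result is a word x
bin matrix of -log10 p, a "landscape" whose peaks mark words
overrepresented among the most unstable transcripts.  Words overlapping
ambiguous bases are excluded from both the counts and the window
population.  No nucleotide-composition bias correction is applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES.encode()):
    _CODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def all_words(k: int) -> list[str]:
    """All 4^k DNA words in lexicographic order."""
    return ["".join(w) for w in itertools.product(_BASES, repeat=k)]


def _encode(sequences: list[str]) -> np.ndarray:
    """Stack sequences into a code matrix padded with -1 (= invalid)."""
    n = len(sequences)
    width = max((len(s) for s in sequences), default=0)
    arr = np.full((n, width), -1, dtype=np.int8)
    for i, s in enumerate(sequences):
        raw = np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)
        arr[i, : len(raw)] = _CODE[raw]
    return arr


def _window_ids(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 word id and validity mask for every window of every row."""
    n, width = codes.shape
    if width < k:
        return np.zeros((n, 0), dtype=np.int64), np.zeros((n, 0), dtype=bool)
    nw = width - k + 1
    ids = np.zeros((n, nw), dtype=np.int64)
    valid = np.ones((n, nw), dtype=bool)
    for j in range(k):
        col = codes[:, j : j + nw]
        ids = ids * 4 + np.maximum(col, 0)
        valid &= col >= 0
    return ids, valid


def count_words(sequences, k: int):
    """Overlapping word counts per sequence and in total.

    ``sequences`` is a mapping id -> sequence or a plain list.  Returns
    ``(totals, per_sequence)`` where totals maps word -> total count and
    per_sequence maps each id (or list position) to its own word -> count
    dict.  Windows touching non-ACGT characters are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(sequences, dict):
        ids_list = list(sequences)
        seqs = [sequences[i] for i in ids_list]
    else:
        seqs = list(sequences)
        ids_list = list(range(len(seqs)))
    if seqs and k > max(len(s) for s in seqs):
        raise ValueError(f"k={k} exceeds every sequence length")
    codes = _encode(seqs)
    word_ids, valid = _window_ids(codes, k)
    words = all_words(k)
    per_sequence = {}
    totals_arr = np.zeros(4**k, dtype=np.int64)
    for i, sid in enumerate(ids_list):
        w = word_ids[i][valid[i]]
        uniq, counts = np.unique(w, return_counts=True)
        per_sequence[sid] = {words[u]: int(c) for u, c in zip(uniq, counts)}
        np.add.at(totals_arr, uniq, counts)
    totals = {words[i]: int(totals_arr[i]) for i in np.nonzero(totals_arr)[0]}
    return totals, per_sequence


def _log_binom(a, b):
    """ln C(a, b) for nonnegative integer arrays (b clipped into range)."""
    b = np.clip(b, 0, a)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _hypergeom_upper_tail(
    leading: np.ndarray, total: np.ndarray, draws: np.ndarray, n_total: int
) -> np.ndarray:
    """P(X >= leading) for X ~ Hypergeom(n_total, total_w, draws_i), per cell.

    Exact suffix sums of the pmf.  Words sharing the same total count
    follow identical distributions at every bin, so the tail table is
    built once per distinct total and indexed by each word's observed
    count; this keeps the cost linear in the number of distinct totals
    instead of the number of words.
    """
    nbins, nwords = leading.shape
    p = np.empty((nbins, nwords))
    for k_tot in np.unique(total):
        cols = np.nonzero(total == k_tot)[0]
        t = np.arange(k_tot + 1)[None, :]
        n = draws[:, None]
        # log pmf = ln C(K,t) + ln C(N-K, n-t) - ln C(N, n), zero off-support
        valid = (n - t >= 0) & (n - t <= n_total - k_tot)
        logpmf = np.where(
            valid,
            _log_binom(k_tot, t) + _log_binom(n_total - k_tot, n - t) - _log_binom(n_total, n),
            -np.inf,
        )
        pmf = np.exp(logpmf)
        tail = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]  # tail[i, c] = P(X >= c)
        tail = np.minimum(tail, 1.0)
        obs = leading[:, cols]
        p[:, cols] = np.take_along_axis(tail, obs, axis=1)
    return p


@dataclass
class WordLandscape:
    """-log10 hypergeometric p per word (columns) and cumulative bin (rows)."""

    words: list[str]
    neglog10_p: np.ndarray  # (nbins, 4^k)
    bin_gene_counts: np.ndarray  # genes in each cumulative bin
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.neglog10_p,
            index=pd.Index(self.bin_gene_counts, name="leading_genes"),
            columns=self.words,
        )


def word_landscape(
    ranked_ids: list[str],
    utr_sequences: dict[str, str],
    k: int,
    nbins: int = 40,
) -> WordLandscape:
    """Cumulative-bin overrepresentation landscape for a ranked UTR list.

    ``ranked_ids`` orders the genes most-decayed first and must be a
    permutation of the sequence keys.  Bin i covers the leading
    ceil(i*N/nbins) genes; the final bin is the whole list, where every
    p-value is 1 by construction.
    """
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    n = len(ranked_ids)
    if n < nbins:
        raise ValueError(f"ranked list ({n}) shorter than nbins ({nbins})")
    if set(ranked_ids) != set(utr_sequences) or n != len(utr_sequences):
        raise ValueError("ranking must be a permutation of the UTR sequence ids")
    seqs = [utr_sequences[g] for g in ranked_ids]
    short = [g for g, s in zip(ranked_ids, seqs) if len(s) < k]
    if short:
        raise ValueError(f"sequences shorter than k={k}: {short[:5]}")

    codes = _encode(seqs)
    word_ids, valid = _window_ids(codes, k)
    windows_per_gene = valid.sum(axis=1)

    bounds = [math.ceil(i * n / nbins) for i in range(1, nbins + 1)]
    nwords = 4**k
    counts = np.zeros((nbins, nwords), dtype=np.int64)
    prev = 0
    for i, b in enumerate(bounds):
        seg_ids = word_ids[prev:b][valid[prev:b]]
        counts[i] = np.bincount(seg_ids, minlength=nwords)
        prev = b
    leading = np.cumsum(counts, axis=0)  # word occurrences in leading genes
    total = leading[-1]  # per-word totals over the whole list
    window_cum = np.cumsum(
        [windows_per_gene[(0 if i == 0 else bounds[i - 1]) : b].sum() for i, b in enumerate(bounds)]
    )
    n_total = int(windows_per_gene.sum())

    # P(X >= observed) for X ~ Hypergeom(N windows, K word occurrences,
    # n windows drawn from the leading genes)
    p = _hypergeom_upper_tail(leading, total, window_cum, n_total)
    neglog = -np.log10(np.maximum(p, 1e-300))
    return WordLandscape(
        words=all_words(k),
        neglog10_p=neglog,
        bin_gene_counts=np.asarray(bounds),
        k=k,
    )


def top_motifs(landscape: WordLandscape, n: int = 5) -> pd.DataFrame:
    """Words ranked by their landscape peak (ties broken lexicographically).

    Returns word, peak -log10 p and the 1-based bin index of the peak.
    ``n`` larger than the number of words returns all words.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    peaks = landscape.neglog10_p.max(axis=0)
    peak_bins = landscape.neglog10_p.argmax(axis=0) + 1
    # words are stored in lexicographic order, so index order breaks ties
    order = np.lexsort((np.arange(len(peaks)), -peaks))[:n]
    return pd.DataFrame(
        {
            "word": [landscape.words[i] for i in order],
            "peak_neglog10_p": peaks[order],
            "peak_bin": peak_bins[order],
            "peak_leading_genes": landscape.bin_gene_counts[peak_bins[order] - 1],
        }
    )


def bonferroni_line(k: int, alpha: float = 0.05) -> float:
    """-log10 of the family-wise threshold alpha / 4^k over all words."""
    return float(-math.log10(alpha / 4**k))


def _check_dna(label: str, seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if any(b not in _BASES for b in seq):
        raise ValueError(f"{label} contains non-ACGT characters: {seq!r}")
    return seq


def seed_match(word: str, mirna_seeds: dict[str, str]) -> list[str]:
    """miRNAs whose seed region the word is complementary to.

    Seeds are given 5'->3' (RNA alphabet accepted); a word of length L
    matches a miRNA when it equals the reverse complement of seed
    positions 2..L+1 (the canonical hexamer/heptamer seed sites).
    """
    word = _check_dna("word", word)
    hits = []
    for name, seed in mirna_seeds.items():
        seed = _check_dna(f"seed {name}", seed)
        region = seed[1 : 1 + len(word)]
        if len(region) == len(word) and word == revcomp(region):
            hits.append(name)
    return hits


def random_sequences(
    n: int, length: int, rng: np.random.Generator, gc: float = 0.5
) -> list[str]:
    """Uniform-random DNA sequences (benchmark fixture material)."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    draws = rng.choice(4, size=(n, length), p=probs)
    lut = np.array(list(_BASES))
    return ["".join(row) for row in lut[draws]]


def plant_word(sequences: list[str], word: str, copies: int, into_first: int) -> list[str]:
    """Overwrite ``copies`` evenly spaced occurrences of ``word`` into the
    first ``into_first`` sequences; returns a new list."""
    out = list(sequences)
    k = len(word)
    for i in range(min(into_first, len(out))):
        s = list(out[i])
        gap = max(k, len(s) // max(copies, 1))
        for c in range(copies):
            start = c * gap
            if start + k <= len(s):
                s[start : start + k] = word
        out[i] = "".join(s)
    return out
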