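"""Promoter scanning with PWMs and TF -> target regulatory pair designation.

A position weight matrix (PWM) is scored against every window of a promoter
sequence (both strands) with the log-likelihood ratio

    score(w) = sum_i log2( pwm[i][w_i] / bg[w_i] )   [bits]

and scores are converted to exact p-values P(score >= s) under the
background model by dynamic programming: per-position score distributions,
discretized to a 1/1000-bit grid, are convolved across positions, so the
p-value of any observed score is a tail sum of the resulting distribution.
The discretization bound on the p-value is at most the background mass of
words within L/2000 bits of the threshold (<= 1e-3 for the packaged
motifs, verified exhaustively in the tests).

Hits in promoters of photosynthesis-related genes are then cross-referenced
with DEG-encoded transcription factors (via an explicit motif -> TF map) to
designate regulatory pairs, ordered by TF fold change ascending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .degs import adjust_pvalues
from .errors import MemeParseError, ValidationError

_BASES = "ACGT"
#: DP score grid resolution: 1/1000 bit
GRID_BITS = 1e-3
# any window summing below this carries the log2(0) sentinel (finite window
# scores are bounded by motif length * 20 bits, i.e. well above this)
_NEG_INF_CUTOFF = -(2**40)


@dataclass
class Pwm:
    """Probability matrix over ACGT, one row per motif position."""

    motif_id: str
    matrix: np.ndarray
    tf_family: str = ""
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValidationError("PWM must be an (L, 4) matrix with L >= 1")
        if np.any(self.matrix < 0):
            raise ValidationError("PWM probabilities must be >= 0")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError("each PWM position must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            motif_id=self.motif_id,
            matrix=self.matrix[::-1, ::-1].copy(),
            tf_family=self.tf_family,
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHit:
    """One scored PWM site: 0-based offset on the + strand of the promoter."""

    motif_id: str
    sequence_id: str
    offset: int
    strand: str
    score_bits: float
    p: float
    q: float = float("nan")


@dataclass
class RegulatoryPair:
    """A DEG-encoded TF linked to a photosynthesis gene through promoter hits."""

    tf_gene: str
    tf_fold_change: float
    tf_fdr: float
    tf_family: str
    tf_description: str
    target_gene: str
    target_description: str
    target_fold_change: float
    target_fdr: float
    hits: list[MotifHit] = field(default_factory=list)


def read_meme_motifs(path, pseudocount: float = 1e-4) -> list[Pwm]:
    """Parse a MEME minimal-format motif file into probability matrices.

    Each probability column gets an additive ``pseudocount`` and is
    renormalized so no probability is exactly zero. Raises
    :class:`MemeParseError` with the offending line number on malformed
    input (non-DNA alphabet, rows not summing to 1 within 1e-3, wrong row
    counts).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    motifs: list[Pwm] = []
    alphabet_seen = False
    i = 0
    n = len(lines)
    if not any(ln.strip().startswith("MEME version") for ln in lines[:5]):
        raise MemeParseError("line 1: missing 'MEME version' header")
    while i < n:
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            alpha = line.split("=", 1)[1].strip()
            if alpha.upper() != "ACGT":
                raise MemeParseError(f"line {i+1}: alphabet {alpha!r} is not DNA (ACGT)")
            alphabet_seen = True
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MemeParseError(f"line {i+1}: MOTIF line without an identifier")
            motif_id = parts[1]
            tf_family = parts[2] if len(parts) > 2 else ""
            # find the letter-probability header
            j = i + 1
            while j < n and not lines[j].strip().startswith("letter-probability matrix"):
                if lines[j].strip().startswith("MOTIF"):
                    raise MemeParseError(
                        f"line {j+1}: motif {motif_id!r} has no letter-probability matrix"
                    )
                j += 1
            if j >= n:
                raise MemeParseError(
                    f"line {i+1}: motif {motif_id!r} has no letter-probability matrix"
                )
            header = lines[j].strip()
            fields = dict(
                zip(header.replace("letter-probability matrix:", "").split()[::2],
                    header.replace("letter-probability matrix:", "").split()[1::2])
            )
            try:
                width = int(fields["w="])
            except (KeyError, ValueError):
                raise MemeParseError(f"line {j+1}: missing or invalid motif width 'w='")
            rows = []
            for r in range(width):
                k = j + 1 + r
                if k >= n or not lines[k].strip():
                    raise MemeParseError(
                        f"line {k+1}: expected {width} matrix rows for {motif_id!r}"
                    )
                try:
                    vals = [float(x) for x in lines[k].split()]
                except ValueError:
                    raise MemeParseError(f"line {k+1}: non-numeric matrix entry")
                if len(vals) != 4:
                    raise MemeParseError(
                        f"line {k+1}: expected 4 probabilities, got {len(vals)}"
                    )
                if abs(sum(vals) - 1.0) > 1e-3:
                    raise MemeParseError(
                        f"line {k+1}: probabilities sum to {sum(vals):.4f}, not 1"
                    )
                rows.append(vals)
            matrix = np.asarray(rows, dtype=float) + pseudocount
            matrix /= matrix.sum(axis=1, keepdims=True)
            motifs.append(Pwm(motif_id=motif_id, matrix=matrix,
                              tf_family=tf_family, pseudocount=pseudocount))
            i = j + width
        i += 1
    if motifs and not alphabet_seen:
        warnings.warn("MEME file lacks an ALPHABET line; assuming ACGT")
    return motifs


def packaged_motifs() -> list[Pwm]:
    """Synthetic stand-in motif set shipped with the package (MEME minimal)."""
    path = resources.files("droughtlight.data") / "synthetic_plant_motifs.meme"
    with resources.as_file(path) as p:
        return read_meme_motifs(p)


def _score_table(pwm: Pwm, background: np.ndarray) -> np.ndarray:
    """Integer per-position scores in millibits; -2**30 marks log2(0) = -inf."""
    with np.errstate(divide="ignore"):
        bits = np.log2(pwm.matrix / background[None, :])
    table = np.where(
        np.isneginf(bits), np.iinfo(np.int64).min // 4,
        np.round(bits / GRID_BITS),
    ).astype(np.int64)
    return table


class ScoreDistribution:
    """Exact DP distribution of the discretized LLR score under the background."""

    def __init__(self, pwm: Pwm, background: Sequence[float]):
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0):
            raise ValidationError("background must be 4 strictly positive frequencies")
        bg = bg / bg.sum()
        self.background = bg
        self.table = _score_table(pwm, bg)
        finite = self.table > np.iinfo(np.int64).min // 8
        # convolve per-position score distributions over the finite range
        cur = np.array([1.0])
        cur_lo = 0
        for i in range(len(pwm)):
            pos_scores = self.table[i][finite[i]]
            pos_probs = bg[finite[i]]
            s_lo = int(pos_scores.min())
            s_hi = int(pos_scores.max())
            nxt = np.zeros(len(cur) + s_hi - s_lo)
            for s, pr in zip(pos_scores, pos_probs):
                nxt[s - s_lo: s - s_lo + len(cur)] += pr * cur
            cur = nxt
            cur_lo += s_lo
        self.min_score = cur_lo
        self.probs = cur
        # survival function over the finite support; words hitting a zero
        # probability column (score -inf) contribute no tail mass
        self.sf = np.concatenate([np.cumsum(cur[::-1])[::-1], [0.0]])

    def score_int(self, word: np.ndarray) -> int:
        """Discretized score of an encoded word (int64 sum; -inf stays huge negative)."""
        return int(self.table[np.arange(len(word)), word].sum())

    def pvalue_int(self, score: int) -> float:
        """P(discretized score >= ``score``) under the background model."""
        if score <= self.min_score:
            return min(1.0, float(self.sf[0]))
        idx = score - self.min_score
        if idx >= len(self.probs):
            return 0.0
        return min(1.0, float(self.sf[idx]))

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_int(int(round(score_bits / GRID_BITS)))


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        out[arr == ord(b)] = i
    bad = (out == -1) & (arr != ord("N"))
    if bad.any():
        raise ValidationError(
            f"sequence contains non-ACGTN character {chr(arr[bad.argmax()])!r}"
        )
    return out


def scan_sequence(
    pwm: Pwm,
    seq: str,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    p_threshold: float = 1e-4,
    sequence_id: str = "",
    collapse: bool = True,
    _dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan both strands of ``seq`` with ``pwm`` and report hits with p <= threshold.

    Hit offsets are 0-based starts on the + strand of the supplied sequence
    for both strands; windows containing N are skipped. Overlapping hits of
    the motif on one promoter are collapsed to the best-p hit unless
    ``collapse=False``. q-values are BH-adjusted over all scanned windows
    (both strands) of this sequence.
    """
    dist = _dist or ScoreDistribution(pwm, background)
    enc = _encode(seq)
    w = len(pwm)
    if w > len(enc):
        return []
    table_fwd = dist.table
    table_rev = table_fwd[::-1, ::-1]  # reverse-complement PWM score table

    n_win = len(enc) - w + 1
    valid = np.ones(n_win, dtype=bool)
    isn = enc < 0
    if isn.any():
        valid = ~(np.convolve(isn.astype(int), np.ones(w, dtype=int), "valid") > 0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)

    raw: list[tuple[int, str, int]] = []  # (offset, strand, int score)
    pvals: list[float] = []
    safe = np.where(windows >= 0, windows, 0)
    for strand, table in (("+", table_fwd), ("-", table_rev)):
        scores = table[np.arange(w)[None, :], safe].sum(axis=1)
        for off in np.nonzero(valid)[0]:
            s = int(scores[off])
            # windows hitting a zero-probability column score -inf: p = 1
            p = 1.0 if s < _NEG_INF_CUTOFF else dist.pvalue_int(s)
            raw.append((int(off), strand, s))
            pvals.append(p)
    if not raw:
        return []
    qvals = adjust_pvalues(np.clip(pvals, 0.0, 1.0), method="BH")
    hits = [
        MotifHit(
            motif_id=pwm.motif_id, sequence_id=sequence_id, offset=off,
            strand=strand, score_bits=s * GRID_BITS, p=p, q=float(q),
        )
        for (off, strand, s), p, q in zip(raw, pvals, qvals)
        if p <= p_threshold
    ]
    hits.sort(key=lambda h: (h.p, h.offset, h.strand))
    if collapse:
        kept: list[MotifHit] = []
        for h in hits:
            if all(
                h.offset + w <= k.offset or k.offset + w <= h.offset
                for k in kept
            ):
                kept.append(h)
        hits = kept
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    motifs: Iterable[Pwm],
    promoters: Mapping[str, str],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """Scan every motif against every promoter; one DP table per motif."""
    all_hits: list[MotifHit] = []
    for pwm in motifs:
        dist = ScoreDistribution(pwm, background)
        for seq_id, seq in promoters.items():
            all_hits.extend(
                scan_sequence(pwm, seq, background, p_threshold,
                              sequence_id=seq_id, _dist=dist)
            )
    return all_hits


def designate_pairs(
    tf_degs: pd.DataFrame,
    hits: Iterable[MotifHit],
    motif2tf: Mapping[str, str],
    target_degs: pd.DataFrame,
    tf_families: Mapping[str, str] | None = None,
    tf_descriptions: Mapping[str, str] | None = None,
    target_descriptions: Mapping[str, str] | None = None,
) -> list[RegulatoryPair]:
    """Cross-reference DEG-encoded TFs with promoter hits into regulatory pairs.

    ``tf_degs`` and ``target_degs`` are DataFrames indexed by gene id with
    columns ``fold_change`` and ``fdr`` (``fold_change`` may be a signed
    linear fold change or a log2 fold change; it is carried through, not
    transformed). Hits whose motif has no TF assignment raise a warning and
    are ignored; hits for TFs absent from ``tf_degs`` or targets absent from
    ``target_degs`` are skipped. One pair is emitted per (TF, target) with
    at least one supporting hit, sorted by TF fold change ascending.
    """
    tf_families = tf_families or {}
    tf_descriptions = tf_descriptions or {}
    target_descriptions = target_descriptions or {}
    grouped: dict[tuple[str, str], list[MotifHit]] = {}
    for hit in hits:
        tf = motif2tf.get(hit.motif_id)
        if tf is None:
            warnings.warn(f"motif {hit.motif_id!r} has no TF assignment; hit ignored")
            continue
        if tf not in tf_degs.index or hit.sequence_id not in target_degs.index:
            continue
        grouped.setdefault((tf, hit.sequence_id), []).append(hit)

    pairs = [
        RegulatoryPair(
            tf_gene=tf,
            tf_fold_change=float(tf_degs.loc[tf, "fold_change"]),
            tf_fdr=float(tf_degs.loc[tf, "fdr"]),
            tf_family=tf_families.get(tf, ""),
            tf_description=tf_descriptions.get(tf, ""),
            target_gene=target,
            target_description=target_descriptions.get(target, ""),
            target_fold_change=float(target_degs.loc[target, "fold_change"]),
            target_fdr=float(target_degs.loc[target, "fdr"]),
            hits=sorted(hl, key=lambda h: (h.offset, h.strand)),
        )
        for (tf, target), hl in grouped.items()
    ]
    pairs.sort(key=lambda p: (p.tf_fold_change, p.tf_gene, p.target_gene))
    return pairs


def summarize_pairs(pairs: Sequence[RegulatoryPair]) -> dict:
    """Totals, counts by TF family and by TF regulation direction.

    Direction is the sign of the TF fold change (up > 0, down < 0). The
    family and direction counts each sum to the total.
    """
    by_family: dict[str, int] = {}
    up = down = 0
    for p in pairs:
        by_family[p.tf_family] = by_family.get(p.tf_family, 0) + 1
        if p.tf_fold_change > 0:
            up += 1
        else:
            down += 1
    return {
        "total": len(pairs),
        "by_family": dict(sorted(by_family.items())),
        "up_regulated_tfs": up,
        "down_regulated_tfs": down,
    }


def tf_deg_fraction(n_tf_degs: int, deg_set_sizes: Iterable[int]) -> float:
    """Percentage of all DEGs that encode transcription factors.

    ``deg_set_sizes`` are the sizes of the (disjoint) DEG sets, e.g. the up-
    and down-regulated counts; returns 100 * n_tf_degs / total.
    """
    total = sum(deg_set_sizes)
    if total <= 0:
        raise ValidationError("total DEG count must be positive")
    if n_tf_degs < 0 or n_tf_degs > total:
        raise ValidationError("TF DEG count must be between 0 and the total")
    return 100.0 * n_tf_degs / total


def load_packaged_pairs() -> list[RegulatoryPair]:
    """The 17 packaged TF -> photosynthesis-gene regulatory pairs.

    Verbatim in-package fixture of the published pair table (TF gene, fold
    change, FDR, family, description, target gene, description, fold
    change, FDR); fold changes are signed linear fold changes as printed.
    """
    path = resources.files("droughtlight.data") / "table1_regulatory_pairs.tsv"
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t")
    return [
        RegulatoryPair(
            tf_gene=r["tf_gene"],
            tf_fold_change=float(r["tf_fold_change"]),
            tf_fdr=float(r["tf_fdr"]),
            tf_family=r["tf_family"],
            tf_description=r["tf_description"],
            target_gene=r["target_gene"],
            target_description=r["target_description"],
            target_fold_change=float(r["target_fold_change"]),
            target_fdr=float(r["target_fdr"]),
        )
        for _, r in table.iterrows()
    ]


def hits_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [h.__dict__ for h in hits],
        columns=["motif_id", "sequence_id", "offset", "strand",
                 "score_bits", "p", "q"],
    )


def pairs_frame(pairs: Sequence[RegulatoryPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf_gene": p.tf_gene, "tf_fold_change": p.tf_fold_change,
                "tf_fdr": p.tf_fdr, "tf_family": p.tf_family,
                "tf_description": p.tf_description,
                "target_gene": p.target_gene,
                "target_description": p.target_description,
                "target_fold_change": p.target_fold_change,
                "target_fdr": p.target_fdr,
                "n_hits": len(p.hits),
            }
            for p in pairs
        ],
        columns=["tf_gene", "tf_fold_change", "tf_fdr", "tf_family",
                 "tf_description", "target_gene", "target_description",
                 "target_fold_change", "target_fdr", "n_hits"],
    )
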