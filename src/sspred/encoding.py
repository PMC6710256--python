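"""Per-residue input encodings: one-hot, plain and entropy-weighted profiles,
clipping, alignment/profile combination, and the 3-state probability
augmentation used by the 8-state cascade.

Profiles are 22 numbers per residue: 20 standard amino-acid frequencies in
the canonical order ``ACDEFGHIKLMNPQRSTVWY``, one pooled frequency for
non-standard/unknown residues, and one gap frequency.  The first 21
components are normalized to sum to 1 over the non-gap characters of the
column; the gap component is normalized independently.

The weighted profile replaces raw counts with per-sequence weights

    W_seq = sum_n -log f[aa_seq(n)]

where f[aa_seq(n)] is the relative frequency of sequence seq's residue at
column n among the non-gap characters of that column, summed over the
non-gap positions of the sequence.  Sequences that diverge more from the
alignment consensus therefore count more, maximizing the entropy of the
resulting profile.  The logarithm base is irrelevant: changing it rescales
every weight by the same constant, which cancels in the normalization.

Clipping overwrites the component of the query's own residue with 1 without
renormalizing.  No information is lost: the pre-clip value of that component
is recoverable as 1 minus the sum of the other 20 of the first 21.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import AA20, AA_INDEX, ValidationError
from .io_formats import Alignment, FormatError, ProteinRecord

#: Component indices within a 22-wide profile row.
NONSTD_COL = 20
GAP_COL = 21

#: Known encoding schemes and their per-residue widths.
SCHEME_WIDTHS = {
    "onehot": 20,
    "plain": 22,
    "weighted": 22,
    "weighted_clipped": 22,
    "concat": 44,
    "ss3_augmented": (25, 47),
}


@dataclass
class EncodedSequence:
    """L x D matrix of per-residue network inputs plus its scheme tag."""

    rows: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2:
            raise ValidationError("encoded rows must be a 2-D array")
        width = SCHEME_WIDTHS.get(self.scheme)
        if width is not None:
            allowed = width if isinstance(width, tuple) else (width,)
            if self.rows.shape[1] not in allowed:
                raise ValidationError(
                    f"scheme {self.scheme!r} expects width {allowed}, "
                    f"got {self.rows.shape[1]}"
                )

    def __len__(self) -> int:
        return self.rows.shape[0]

    @property
    def width(self) -> int:
        return self.rows.shape[1]


def _aa_slot(ch: str) -> int:
    """Column slot of a residue character: its own slot, or the pooled one."""
    return AA_INDEX.get(ch, NONSTD_COL)


def onehot_encode(record: ProteinRecord) -> EncodedSequence:
    """One-hot encoding over the 20 standard residues.

    Non-standard residues (B, J, O, U, Z, X) become all-zero vectors.
    """
    rows = np.zeros((len(record), 20))
    for i, ch in enumerate(record.sequence):
        j = AA_INDEX.get(ch)
        if j is not None:
            rows[i, j] = 1.0
    return EncodedSequence(rows, "onehot")


def _column_slots(aln: Alignment) -> list[str]:
    rows = aln.all_rows()
    if not rows:
        raise FormatError("alignment has no rows")
    return rows


def plain_profile(aln: Alignment) -> EncodedSequence:
    """Column frequencies over the alignment rows (query included).

    Per column, the first 21 components are character counts normalized over
    non-gap characters only; the 22nd is the fraction of gap characters over
    all rows.
    """
    rows = _column_slots(aln)
    L = len(aln.query)
    out = np.zeros((L, 22))
    for j in range(L):
        counts = np.zeros(21)
        gaps = 0
        for row in rows:
            ch = row[j]
            if ch == "-":
                gaps += 1
            else:
                counts[_aa_slot(ch)] += 1
        nongap = counts.sum()
        assert nongap > 0, "column with no non-gap characters (query row is ungapped)"
        out[j, :21] = counts / nongap
        out[j, GAP_COL] = gaps / len(rows)
    return EncodedSequence(out, "plain")


def sequence_weights(aln: Alignment) -> np.ndarray:
    """Entropy-maximizing weight of each alignment row (query row first).

    W_seq sums ``-log`` of the column relative frequency (among non-gap
    characters) of the row's own residue, over the row's non-gap positions;
    natural log.  If every weight is zero (all rows identical), falls back
    to uniform weights 1/n_rows.
    """
    rows = _column_slots(aln)
    L = len(aln.query)
    n = len(rows)
    # Per-column relative frequencies of the 21 residue classes.
    freqs = np.zeros((L, 21))
    for j in range(L):
        counts = np.zeros(21)
        for row in rows:
            ch = row[j]
            if ch != "-":
                counts[_aa_slot(ch)] += 1
        total = counts.sum()
        if total > 0:
            freqs[j] = counts / total
    w = np.zeros(n)
    for r, row in enumerate(rows):
        acc = 0.0
        for j, ch in enumerate(row):
            if ch != "-":
                acc -= math.log(freqs[j, _aa_slot(ch)])
        w[r] = acc
    if not np.any(w > 0):
        w = np.full(n, 1.0 / n)
    return w


def _coverage(row: str) -> tuple[int, int]:
    """Span [first, last] of non-gap positions of a row; (-1, -2) if all gaps."""
    first = next((i for i, ch in enumerate(row) if ch != "-"), -1)
    if first < 0:
        return -1, -2
    last = len(row) - 1 - next(i for i, ch in enumerate(reversed(row)) if ch != "-")
    return first, last


def weighted_profile(aln: Alignment, weights: np.ndarray | None = None) -> EncodedSequence:
    """Entropy-weighted profile: counts replaced by per-sequence weight sums.

    Residue components are normalized as in :func:`plain_profile`.  The gap
    component is also weight-based but ignores *external* gaps — the maximal
    gap runs touching a row's first or last position — in both the numerator
    and the denominator of the gap fraction.

    ``weights`` overrides the computed :func:`sequence_weights` (one value
    per row, query row first).  Because of the normalization the profile is
    invariant to a common rescaling of the weights — in particular to the
    logarithm base used in W_seq.
    """
    rows = _column_slots(aln)
    w = sequence_weights(aln) if weights is None else np.asarray(weights, float)
    if w.shape != (len(rows),):
        raise ValidationError(f"need one weight per row, got shape {w.shape}")
    L = len(aln.query)
    spans = [_coverage(row) for row in rows]
    out = np.zeros((L, 22))
    for j in range(L):
        acc = np.zeros(21)
        gap_w = 0.0
        cover_w = 0.0
        for r, row in enumerate(rows):
            ch = row[j]
            if ch != "-":
                acc[_aa_slot(ch)] += w[r]
                cover_w += w[r]
            else:
                first, last = spans[r]
                if first <= j <= last:  # internal gap
                    gap_w += w[r]
                    cover_w += w[r]
        total = acc.sum()
        assert total > 0, "column with no non-gap characters (query row is ungapped)"
        out[j, :21] = acc / total
        out[j, GAP_COL] = gap_w / cover_w if cover_w > 0 else 0.0
    return EncodedSequence(out, "weighted")


def clip(enc: EncodedSequence, query: ProteinRecord) -> EncodedSequence:
    """Set the query residue's profile component to 1, leaving the rest alone.

    For non-standard query residues the pooled 21st component is set.  The
    overwrite is deliberately not renormalized, so the pre-clip value stays
    recoverable as 1 minus the sum of the other 20 of the first 21.
    """
    if enc.width != 22:
        raise ValidationError(f"clip expects a 22-wide profile, got width {enc.width}")
    if len(enc) != len(query):
        raise ValidationError(
            f"profile length {len(enc)} != query length {len(query)}"
        )
    rows = enc.rows.copy()
    for i, ch in enumerate(query.sequence):
        rows[i, _aa_slot(ch)] = 1.0
    return EncodedSequence(rows, "weighted_clipped")


def unclip_value(row: np.ndarray, query_slot: int) -> float:
    """Recover a clipped component: 1 minus the sum of the other 20 of 21."""
    others = row[:21].sum() - row[query_slot]
    return 1.0 - others


def combine_alignments(a: Alignment, b: Alignment, mode: str) -> Alignment:
    """Union or intersection of two alignments over the same query.

    union:
        concatenated homolog rows of both alignments, de-duplicated on the
        aligned row string; the query appears once.
    intersection:
        homolog rows of ``a`` whose ungapped sequence also occurs among the
        rows of ``b`` (the query always survives).
    """
    if a.query.sequence != b.query.sequence:
        raise ValidationError("alignments have different query sequences")
    if mode == "union":
        seen: set[str] = set()
        rows = []
        for row in a.rows + b.rows:
            if row not in seen and row != a.query.sequence:
                seen.add(row)
                rows.append(row)
    elif mode == "intersection":
        b_seqs = {row.replace("-", "") for row in b.rows}
        rows = [row for row in a.rows if row.replace("-", "") in b_seqs]
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    return Alignment(query=a.query, rows=rows, include_query_row=True)


def average_profiles(p: EncodedSequence, q: EncodedSequence) -> EncodedSequence:
    """Componentwise mean of two equal-length 22-wide profiles."""
    if p.width != 22 or q.width != 22:
        raise ValidationError("average_profiles expects 22-wide profiles")
    if len(p) != len(q):
        raise ValidationError(f"profile lengths differ: {len(p)} vs {len(q)}")
    return EncodedSequence((p.rows + q.rows) / 2.0, p.scheme)


def concat_profiles(p: EncodedSequence, q: EncodedSequence) -> EncodedSequence:
    """Per-row concatenation of two 22-wide profiles into a 44-wide encoding."""
    if p.width != 22 or q.width != 22:
        raise ValidationError("concat_profiles expects 22-wide profiles")
    if len(p) != len(q):
        raise ValidationError(f"profile lengths differ: {len(p)} vs {len(q)}")
    return EncodedSequence(np.hstack([p.rows, q.rows]), "concat")


def augment_with_ss3(enc: EncodedSequence, ss3_probs: np.ndarray) -> EncodedSequence:
    """Concatenate 3-state class probabilities to a profile (profile first).

    Used by the 8-state cascade: 22-wide members become 25 inputs, 44-wide
    (concatenated) members become 47.  Each probability row must sum to 1
    within 1e-6.
    """
    ss3_probs = np.asarray(ss3_probs, dtype=float)
    if enc.width not in (22, 44):
        raise ValidationError(
            f"augmentation expects a 22- or 44-wide profile, got {enc.width}"
        )
    if ss3_probs.shape != (len(enc), 3):
        raise ValidationError(
            f"ss3 probabilities must be {len(enc)}x3, got {ss3_probs.shape}"
        )
    sums = ss3_probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6) or np.any(ss3_probs < -1e-12):
        raise ValidationError("ss3 probability rows must be distributions")
    return EncodedSequence(np.hstack([enc.rows, ss3_probs]), "ss3_augmented")
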