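"""Synthetic desk-scale data with the statistical structure the predictor
assumes: secondary-structure segments with class-dependent lengths,
class-conditioned residue emission, and simulated homolog alignments whose
profiles carry learnable signal.

The generator is a semi-Markov chain over the three coarse classes: a class
is drawn (never repeating the previous one), a segment length is drawn from
a geometric distribution with the class's mean, and each position inside
the segment receives an 8-state sub-label from the class's sub-state
distribution.  Residues are then emitted from a per-class amino-acid
propensity table, and homologs are simulated by substituting residues
(drawn from the emitting class's propensity row) and deleting them to gaps
at configurable rates.  Two pseudo-sources with different depths and
substitution rates stand in for the two alignment pipelines real profiles
come from, so source-combination experiments (average, union, intersection,
concatenation) are meaningful.

Defaults: 200 proteins of length 50-150; mean segment lengths H:10, E:5,
C:6 and class weights 38/22/40% helix/sheet/coil, echoing the composition
of structure-derived training sets; sub-state splits within each class
likewise follow those compositions (e.g. most helix residues are H, a few
G, almost no I).  Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA20, map_8_to_3
from .io_formats import Alignment, ProteinRecord

#: Default sub-state distribution inside each coarse class, proportioned
#: like the composition of large structure-derived sets.
DEFAULT_SUBSTATES = {
    "H": {"H": 0.9056, "G": 0.0939, "I": 0.0005},
    "E": {"E": 0.9512, "B": 0.0488},
    "C": {"C": 0.5051, "T": 0.2761, "S": 0.2188},
}

#: Residues favoured by each class (multiplicatively) in the default
#: emission table: classic helix formers, beta-branched/aromatic residues,
#: and turn/loop residues.
_FAVOURED = {"H": "ALMEQK", "E": "VIFYWT", "C": "GPNDS"}


def default_propensity_table(strength: float = 2.5) -> dict[str, np.ndarray]:
    """Per-class emission distributions over the 20 standard residues.

    ``strength`` is the multiplicative preference of a class for its
    favoured residues; 1.0 gives a uniform, uninformative table.
    """
    table = {}
    for cls, favoured in _FAVOURED.items():
        w = np.ones(len(AA20))
        for aa in favoured:
            w[AA20.index(aa)] *= strength
        table[cls] = w / w.sum()
    return table


@dataclass
class SourceConfig:
    """Homolog-simulation settings of one pseudo alignment source."""

    n_homologs: int = 30
    sub_rate: float = 0.50
    indel_rate: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must be in [0, 1]")


@dataclass
class SyntheticConfig:
    n_proteins: int = 200
    length_range: tuple[int, int] = (50, 150)
    mean_segment_length: dict[str, float] = field(
        default_factory=lambda: {"H": 10.0, "E": 5.0, "C": 6.0}
    )
    class_weights: dict[str, float] = field(
        default_factory=lambda: {"H": 0.38, "E": 0.22, "C": 0.40}
    )
    substates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUBSTATES.items()}
    )
    propensity_table: dict[str, np.ndarray] = field(
        default_factory=default_propensity_table
    )
    source_a: SourceConfig = field(default_factory=SourceConfig)
    source_b: SourceConfig = field(
        default_factory=lambda: SourceConfig(n_homologs=10, sub_rate=0.35)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, dist in self.substates.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"sub-state distribution of {cls!r} sums to {total}")
        for cls, row in self.propensity_table.items():
            row = np.asarray(row, float)
            if abs(row.sum() - 1.0) > 1e-6:
                raise ValueError(f"propensity row of {cls!r} is not normalized")
            self.propensity_table[cls] = row


def _embedded_rates(target_visits: np.ndarray) -> np.ndarray:
    """Class-proposal rates whose no-self-transition chain visits classes
    with the requested stationary frequencies.

    The chain picks the next class j != i with probability
    rho_j / sum_{k != i} rho_k; excluding the previous class biases the
    visit distribution away from rho, so rho is solved by fixed-point
    iteration to make the stationary visit distribution equal the target.
    """
    pi = target_visits / target_visits.sum()
    if np.count_nonzero(pi) <= 1:
        return pi
    rho = pi.copy()
    for _ in range(200):
        S = rho.sum()
        denom = np.maximum(S - rho, 1e-12)
        A = np.array(
            [sum(pi[i] / denom[i] for i in range(len(pi)) if i != j)
             for j in range(len(pi))]
        )
        new = np.where(A > 0, pi / np.maximum(A, 1e-12), 0.0)
        new = new / new.sum()
        if np.max(np.abs(new - rho)) < 1e-12:
            rho = new
            break
        rho = new
    return rho


def generate_ss(length: int, cfg: SyntheticConfig, rng: np.random.Generator) -> str:
    """Semi-Markov 8-state label string of a given length.

    Segment classes are visited (never repeating the previous class) with
    frequencies calibrated so residue-level fractions approach the
    configured class weights; segment lengths are geometric with the class
    mean; sub-states are drawn per position from the class's sub-state
    distribution.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    classes = list(cfg.class_weights)
    visits = np.array(
        [cfg.class_weights[c] / cfg.mean_segment_length[c] for c in classes]
    )
    rates = _embedded_rates(visits)
    out: list[str] = []
    prev: str | None = None
    while len(out) < length:
        w = rates.copy()
        if prev is not None:
            w[classes.index(prev)] = 0.0
        if w.sum() == 0:  # single-class config: allow self-transition
            w = rates.copy()
        cls = classes[rng.choice(len(classes), p=w / w.sum())]
        seg_len = 1 + rng.geometric(1.0 / cfg.mean_segment_length[cls]) - 1
        seg_len = min(seg_len, length - len(out))
        subs = list(cfg.substates[cls])
        probs = np.array([cfg.substates[cls][s] for s in subs])
        out.extend(subs[i] for i in rng.choice(len(subs), size=seg_len, p=probs))
        prev = cls
    return "".join(out)


def emit_sequence(
    ss8: str, propensity_table: dict[str, np.ndarray], rng: np.random.Generator
) -> str:
    """Residues drawn per position from the coarse class's propensity row."""
    ss3 = map_8_to_3(ss8)
    out = []
    for cls in ss3:
        row = propensity_table[cls]
        out.append(AA20[rng.choice(len(AA20), p=row)])
    return "".join(out)


def simulate_homologs(
    record: ProteinRecord,
    n: int,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    propensity_table: dict[str, np.ndarray] | None = None,
) -> Alignment:
    """Simulate a query-anchored alignment of n homologs.

    Per homolog and position: a gap with probability ``indel_rate``,
    otherwise a substitution with probability ``sub_rate`` drawn from the
    emitting class's propensity row, otherwise the query residue.  No
    insertion states are generated, so rows stay in query coordinates.
    """
    if record.ss8 is None and sub_rate > 0:
        raise ValueError("homolog simulation needs ss8 labels to draw substitutions")
    table = propensity_table if propensity_table is not None else default_propensity_table()
    ss3 = map_8_to_3(record.ss8) if record.ss8 is not None else None
    L = len(record)
    rows = []
    for _ in range(n):
        chars = []
        for j, aa in enumerate(record.sequence):
            if rng.random() < indel_rate:
                chars.append("-")
            elif rng.random() < sub_rate:
                row = table[ss3[j]]
                chars.append(AA20[rng.choice(len(AA20), p=row)])
            else:
                chars.append(aa)
        rows.append("".join(chars))
    return Alignment(query=record, rows=rows, include_query_row=True)


@dataclass
class SyntheticDataset:
    """Labelled records plus one simulated alignment per record and source."""

    records: list[ProteinRecord]
    alignments_a: list[Alignment]
    alignments_b: list[Alignment]


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset: labels, sequences and both pseudo-sources.

    Fully deterministic from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    records = []
    alns_a = []
    alns_b = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        ss8 = generate_ss(length, cfg, rng)
        seq = emit_sequence(ss8, cfg.propensity_table, rng)
        rec = ProteinRecord(id=f"syn{i:04d}", sequence=seq, ss8=ss8)
        records.append(rec)
        alns_a.append(
            simulate_homologs(
                rec, cfg.source_a.n_homologs, cfg.source_a.sub_rate,
                cfg.source_a.indel_rate, rng, cfg.propensity_table,
            )
        )
        alns_b.append(
            simulate_homologs(
                rec, cfg.source_b.n_homologs, cfg.source_b.sub_rate,
                cfg.source_b.indel_rate, rng, cfg.propensity_table,
            )
        )
    return SyntheticDataset(records=records, alignments_a=alns_a, alignments_b=alns_b)
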