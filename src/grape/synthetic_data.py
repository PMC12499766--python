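"""Synthetic TCR–epitope repertoires with planted, recoverable structure.

The generator emulates the bipartite regime of public TCR–epitope
databases: a few epitopes, many CDR3β sequences, interaction densities in
the 1e-3 range, and extreme per-epitope imbalance.  Ground truth is a
motif-containment rule: each epitope carries a short motif (implanted in
its own sequence) and a TCR truly binds an epitope iff the TCR contains
that motif.  This makes the signal exact, decodable from k-mer count
features, and independent of graph structure, so gains from the graph and
attention machinery are attributable.  Observed positive pairs are a
density-targeted subsample of the true pairs, and labels are flipped
independently with probability ε to emulate curation noise.

CDR3β sequences follow the cosmetic C...F flanking convention; no model
component depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import AMINO_ACIDS, InteractionRecord


@dataclass(frozen=True)
class SimConfig:
    n_tcr: int = 500
    n_epitope: int = 20
    tcr_length: tuple = (10, 20)
    epitope_length: tuple = (8, 11)
    motif_length: int = 3
    label_noise: float = 0.05       # ε, independent label-flip probability
    # target |positives| / (n_tcr × n_epitope); the default puts mean TCR
    # degree at 1.0, the sparse regime of the public databases (their 1e-3
    # densities arise from hundreds of epitopes, not lower TCR degree)
    density: float = 0.05
    eval_ratio: float = 1.0         # negatives per positive in eval sets
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must lie in (0, 1]")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label-flip probability must lie in [0, 0.5)")
        if min(self.tcr_length) < self.motif_length + 2:
            raise ValueError("TCR length must fit flanks plus the motif")
        if min(self.epitope_length) < self.motif_length:
            raise ValueError("epitope length must be >= motif length")


@dataclass
class SimOutput:
    records: list
    motifs: dict                    # epitope sequence -> motif
    truth: set = field(repr=False)  # {(tcr, epitope)} true binding pairs
    tcr_universe: list = field(default_factory=list)   # all repertoire TCRs
    config: SimConfig = None
    seed: int = 0

    @property
    def tcrs(self) -> list:
        """TCRs appearing in emitted records (a subset of the universe)."""
        return sorted({r.tcr for r in self.records})

    @property
    def epitopes(self) -> list:
        return sorted(self.motifs)


def _random_seq(rng, length) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _implant(seq: str, motif: str, rng, lo: int = 0, hi: int | None = None) -> str:
    hi = len(seq) if hi is None else hi
    start = int(rng.integers(lo, hi - len(motif) + 1))
    return seq[:start] + motif + seq[start + len(motif):]


def simulate_repertoire(config: SimConfig | None = None) -> SimOutput:
    """Generate a repertoire under the motif-containment binding rule."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    # distinct motif per epitope
    motifs: list[str] = []
    seen = set()
    while len(motifs) < config.n_epitope:
        m = _random_seq(rng, config.motif_length)
        if m not in seen:
            seen.add(m)
            motifs.append(m)

    # epitopes carry their motif as a substring
    epitopes: list[str] = []
    used = set()
    for m in motifs:
        while True:
            length = int(rng.integers(*config.epitope_length, endpoint=True))
            seq = _implant(_random_seq(rng, length), m, rng)
            if seq not in used:
                used.add(seq)
                epitopes.append(seq)
                break

    tcrs: list[str] = []
    used_t = set()
    while len(tcrs) < config.n_tcr:
        length = int(rng.integers(*config.tcr_length, endpoint=True))
        seq = "C" + _random_seq(rng, length - 2) + "F"
        if seq not in used_t:
            used_t.add(seq)
            tcrs.append(seq)

    target = int(round(config.density * config.n_tcr * config.n_epitope))
    max_pairs = config.n_tcr * config.n_epitope
    if target > max_pairs:
        raise ValueError(
            f"density {config.density} unachievable: at most {max_pairs} pairs"
        )

    def tcr_row(t: str) -> set:
        return {ei for ei, m in enumerate(motifs) if m in t}

    rows = [tcr_row(t) for t in tcrs]  # per-TCR set of bound epitope indices

    def n_true() -> int:
        return sum(len(r) for r in rows)

    # implant motifs into TCR middles until the target is reachable
    guard = 0
    while n_true() < target:
        guard += 1
        if guard > 20 * max_pairs:
            raise ValueError(
                f"density {config.density} unachievable; reached only "
                f"{n_true() / max_pairs:.4f}"
            )
        ti = int(rng.integers(config.n_tcr))
        ei = int(rng.integers(config.n_epitope))
        if ei in rows[ti]:
            continue
        new_t = _implant(tcrs[ti], motifs[ei], rng,
                         lo=1, hi=len(tcrs[ti]) - 1)
        if new_t in used_t:
            continue
        used_t.discard(tcrs[ti])
        used_t.add(new_t)
        tcrs[ti] = new_t
        rows[ti] = tcr_row(new_t)

    true_pairs = [(tcrs[ti], epitopes[ei])
                  for ti in range(config.n_tcr) for ei in sorted(rows[ti])]
    order = rng.permutation(len(true_pairs))
    sampled = [true_pairs[int(i)] for i in order[:target]]
    records = []
    for t, e in sampled:
        label = 1
        if rng.random() < config.label_noise:
            label = 0
        records.append(InteractionRecord(t, e, label, source="synthetic"))
    rng.shuffle(records)
    return SimOutput(records=records,
                     motifs=dict(zip(epitopes, motifs)),
                     truth=set(true_pairs),
                     tcr_universe=sorted(tcrs),
                     config=config, seed=config.seed)


def make_eval_pairs(sim: SimOutput, ratio: float = 1.0, seed: int = 0,
                    exclude=()) -> list:
    """Evaluation table: all positive records plus ratio× true negatives.

    Negatives are pairs that genuinely do not bind under the planted rule,
    disjoint from the observed records and from ``exclude`` (e.g. the
    training negative set).
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    positives = [r for r in sim.records if r.label == 1]
    n_neg = int(round(ratio * len(positives)))
    observed = {(r.tcr, r.epitope) for r in sim.records}
    excluded = observed | set(exclude) | sim.truth
    tcrs = sim.tcr_universe or sim.tcrs
    epitopes = sim.epitopes
    candidates = [
        (t, e) for t in tcrs for e in epitopes if (t, e) not in excluded
    ]
    if len(candidates) < n_neg:
        raise ValueError(
            f"insufficient true negatives: need {n_neg}, have {len(candidates)}"
        )
    chosen = rng.choice(len(candidates), size=n_neg, replace=False)
    negatives = [
        InteractionRecord(*candidates[int(i)], 0, source="synthetic-neg")
        for i in chosen
    ]
    table = positives + negatives
    rng.shuffle(table)
    return table


def records_from_counts(n_tcr: int, n_epitope: int,
                        n_pairs: int) -> list:
    """Positives-only record list with exact unique-sequence counts.

    Reconstructs the shape of a published dataset summary (so many unique
    TCRs, epitopes, and positive pairs) with synthetic sequences — enough
    to recompute interaction densities from printed count tables.  Requires
    n_tcr ≤ n_pairs ≤ 2·n_tcr and n_epitope ≤ n_tcr (the regime of the
    public TCR-epitope databases).
    """
    if not (n_tcr <= n_pairs <= 2 * n_tcr and 2 <= n_epitope <= n_tcr):
        raise ValueError("counts outside the supported regime")

    def seq(prefix_idx: int, idx: int) -> str:
        digits = []
        for _ in range(8):
            digits.append(AMINO_ACIDS[idx % 20])
            idx //= 20
        return AMINO_ACIDS[prefix_idx] + "".join(digits)

    records = [
        InteractionRecord(seq(0, i), seq(1, i % n_epitope), 1)
        for i in range(n_tcr)
    ]
    records += [
        InteractionRecord(seq(0, j), seq(1, (j + 1) % n_epitope), 1)
        for j in range(n_pairs - n_tcr)
    ]
    return records


def provenance(sim: SimOutput) -> dict:
    """Config echo + seed, sufficient to regenerate bit-identically."""
    return {"config": asdict(sim.config), "seed": sim.seed,
            "motifs": sim.motifs}
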