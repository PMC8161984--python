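"""Synthetic mitogenome-like populations and precision/recall evaluation.

The generator emulates the study conditions used to benchmark node-based
variant detection: a random (or supplied) reference of mitogenome scale
(~16.5 kb) and a population of samples, each carrying a configured number of
substitutions, deletions and insertions placed uniformly at non-overlapping
positions, with indel lengths uniform on [1, 49] bp.  Calls are scored
against the simulated truth by location-mapped or type-mapped matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .graph import Genome
from .variants import DEL, INS, SUB, UNSURE, LocusVariant

__all__ = [
    "SimConfig",
    "TruthVariant",
    "EvalReport",
    "random_reference",
    "simulate_population",
    "evaluate_calls",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition knobs for one simulated population.

    Defaults follow the benchmark protocol: 10 samples including the
    reference, per-sample variant counts chosen per experiment, indel
    lengths on [1, 49] bp.
    """

    n_samples: int = 10               # reference included
    snp_count: int = 100
    del_count: int = 0
    ins_count: int = 0
    indel_len_range: tuple[int, int] = (1, 49)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if min(self.snp_count, self.del_count, self.ins_count) < 0:
            raise ValueError("variant counts must be non-negative")
        lo, hi = self.indel_len_range
        if lo < 1 or hi >= 50:
            raise ValueError("indel lengths must stay in [1, 49] bp")


@dataclass(frozen=True)
class TruthVariant:
    sample_id: str
    refpos: int            # 1-based; anchor base for indels
    vartype: int           # 1 sub | 2 del | 3 ins
    ref_allele: str
    alt_allele: str


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    mode: str
    precision: float = field(init=False)
    recall: float = field(init=False)

    def __post_init__(self) -> None:
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0


def random_reference(length: int = 16569, seed: int = 0, sample_id: str = "REF") -> Genome:
    """A uniform-random ACGT reference of mitogenome scale."""
    rng = np.random.default_rng([seed, 0])
    return Genome(sample_id, "".join(rng.choice(_BASES, size=length)))


def simulate_population(
    reference: Genome, config: SimConfig
) -> tuple[list[Genome], list[TruthVariant]]:
    """Mutate the reference into a population plus its truth set.

    Event footprints within one sample never overlap (a 1-bp guard flank
    keeps indels from touching), positions are uniform, substitution alleles
    uniform over the three alternatives, and everything is deterministic for
    a fixed seed.
    """
    # seeded on its own stream so a population seeded like its reference
    # cannot replay the reference's base stream (which would plant long
    # artificial repeats via inserted segments)
    rng = np.random.default_rng([config.seed, 1])
    ref = reference.sequence
    n = len(ref)
    genomes: list[Genome] = [reference]
    truth: list[TruthVariant] = []
    lo, hi = config.indel_len_range
    for i in range(1, config.n_samples):
        sid = f"S{i}"
        events = _place_events(rng, n, config, lo, hi)
        seq = ref
        for pos, typ, length in sorted(events, reverse=True):
            if typ == SUB:
                old = seq[pos - 1]
                new = str(rng.choice(_BASES[_BASES != old]))
                seq = seq[: pos - 1] + new + seq[pos:]
                truth.append(TruthVariant(sid, pos, SUB, old, new))
            elif typ == DEL:
                anchor = seq[pos - 1]
                removed = seq[pos - 1 : pos + length]
                seq = seq[:pos] + seq[pos + length :]
                truth.append(TruthVariant(sid, pos, DEL, removed, anchor))
            else:
                anchor = seq[pos - 1]
                ins = "".join(rng.choice(_BASES, size=length))
                seq = seq[:pos] + ins + seq[pos:]
                truth.append(TruthVariant(sid, pos, INS, anchor, anchor + ins))
        genomes.append(Genome(sid, seq))
    truth.sort(key=lambda t: (t.refpos, t.sample_id))
    return genomes, truth


def _place_events(rng, n, config, lo, hi) -> list[tuple[int, int, int]]:
    """(position, type, length) triples with non-overlapping footprints."""
    events: list[tuple[int, int, int]] = []
    occupied: set[int] = set()
    want = (
        [(SUB, 0)] * config.snp_count
        + [(DEL, None)] * config.del_count
        + [(INS, None)] * config.ins_count
    )
    for typ, _ in want:
        length = 0 if typ == SUB else int(rng.integers(lo, hi + 1))
        placed = False
        for _ in range(10000):
            # indel anchor needs a base before it; keep footprints off the ends
            pos = int(rng.integers(2, n - hi - 1))
            span = range(pos - 1, pos + (length if typ != SUB else 0) + 2)
            if any(p in occupied for p in span):
                continue
            occupied.update(span)
            events.append((pos, typ, length))
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place all requested variants without overlap; "
                "reference too short for the requested counts"
            )
    return events


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_calls(
    calls: Sequence[LocusVariant],
    truth: Sequence[TruthVariant],
    mode: str = "location",
    tolerance: Optional[int] = None,
) -> EvalReport:
    """Score calls against simulation truth.

    Location mode matches on reference position within a tolerance (default 0
    for substitutions, 1 for indels — left-anchoring ambiguity); type mode
    additionally requires the variant types to agree, with vartype 4 (unsure
    indel) accepted for either indel type.  Precision counts matched calls,
    recall counts matched truth records (distinct loci).
    """
    if mode not in ("location", "type"):
        raise ValueError("mode must be 'location' or 'type'")

    def tol(vt: int) -> int:
        if tolerance is not None:
            return tolerance
        return 0 if vt == SUB else 1

    truth_loci = {}
    for t in truth:
        truth_loci.setdefault((t.refpos, t.vartype), set()).add(t.sample_id)
    positions = sorted({t.refpos for t in truth})
    by_pos: dict[int, set[int]] = {}
    for t in truth:
        by_pos.setdefault(t.refpos, set()).add(t.vartype)

    matched_truth: set[int] = set()
    tp = fp = 0
    for c in calls:
        hit = False
        for p in range(c.refpos - tol(c.vartype), c.refpos + tol(c.vartype) + 1):
            if p not in by_pos:
                continue
            if mode == "type" and not _types_agree(c.vartype, by_pos[p]):
                continue
            hit = True
            matched_truth.add(p)
        if hit:
            tp += 1
        else:
            fp += 1
    fn = len(positions) - len(matched_truth)
    return EvalReport(tp=tp, fp=fp, fn=fn, mode=mode)


def _types_agree(call_type: int, truth_types: set[int]) -> bool:
    if call_type in truth_types:
        return True
    if call_type == UNSURE and (DEL in truth_types or INS in truth_types):
        return True
    return False
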