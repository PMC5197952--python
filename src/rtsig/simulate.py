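"""Synthetic RNA-Seq pileups with planted RT signatures.

The generator emulates the read evidence left by modified ribonucleotides:

* *misincorporation* — at a planted site, each covering read miscalls the
  base with a chosen probability and base composition;
* *RT arrest* — a read that would read through a planted site is truncated,
  with the planted probability, so that its leftmost aligned base is one
  position downstream of the site.  This mirrors abortive-cDNA capture
  protocols, where each aborted cDNA is sequenced as a read starting at
  site+1, and makes the read-start/coverage quotient at site+1 a direct
  estimator of the planted arrest fraction.

Everything else is deliberately plain: uniform read placement (no 3' bias),
i.i.d. background miscalls, constant base qualities, no PCR duplicates, no
splicing.  Output is a valid position-sorted SAM with header, a FASTA
reference, and a plain-text truth table; identical spec + seed reproduce
the SAM byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth modification site planted into simulated reads."""

    pos: int  # 1-based
    mismatch_fraction: float = 0.0
    mismatch_profile: tuple[float, float, float, float] | None = None  # over A,C,G,T
    arrest_fraction: float = 0.0
    label: str = ""
    ref_index: int = 1

    def __post_init__(self):
        if not 0 <= self.mismatch_fraction <= 1:
            raise ValueError("mismatch_fraction must be in [0, 1]")
        if not 0 <= self.arrest_fraction <= 1:
            raise ValueError("arrest_fraction must be in [0, 1]")
        if self.mismatch_profile is not None:
            if abs(sum(self.mismatch_profile) - 1.0) > 1e-9:
                raise ValueError("mismatch_profile must sum to 1")


@dataclass
class SimulationSpec:
    reference_length: int = 10_000
    n_references: int = 1
    coverage_target: float = 500.0
    read_length: int = 100
    error_rate: float = 0.005
    sites: list[PlantedSite] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.reference_length < self.read_length:
            raise ValueError("reference shorter than the read length")
        seen = set()
        for s in self.sites:
            if not 1 <= s.pos <= self.reference_length:
                raise ValueError(f"planted site at {s.pos} beyond the reference")
            key = (s.ref_index, s.pos)
            if key in seen:
                raise ValueError(f"duplicate planted site at {key}")
            seen.add(key)


def generate_reference(length: int, rng: np.random.Generator) -> str:
    """Uniform random sequence over A/C/G/T."""
    return "".join(rng.choice(BASES, size=length))


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def _simulate_reference_reads(spec, ref_seq: str, ref_index: int, rng):
    """Yield (start0, bases) read tuples for one reference."""
    L, R = len(ref_seq), spec.read_length
    n_reads = int(round(spec.coverage_target * L / R))
    starts = rng.integers(0, L - R + 1, size=n_reads)
    ref_arr = np.frombuffer(ref_seq.encode("ascii"), dtype="S1")

    sites = sorted((s for s in spec.sites if s.ref_index == ref_index),
                   key=lambda s: s.pos)
    arrest_sites = [s for s in sites if s.arrest_fraction > 0]
    mm_sites = [s for s in sites if s.mismatch_fraction > 0]
    profiles = {}
    for s in mm_sites:
        if s.mismatch_profile is not None:
            profiles[s.pos] = np.asarray(s.mismatch_profile, dtype=float)
        else:  # uniform over the three non-reference bases
            w = np.full(4, 1 / 3)
            w[np.argmax(BASES == ref_seq[s.pos - 1])] = 0.0
            profiles[s.pos] = w

    reads = []
    for s0 in starts:
        s0 = int(s0)
        e0 = s0 + R  # exclusive
        # RT arrest: truncate at the leftmost planted blocker the read
        # would traverse, with the planted probability; the truncated read
        # then starts at site+1 (1-based), i.e. 0-based index site.pos
        for site in arrest_sites:
            t0 = site.pos  # 0-based index of the position just downstream
            if t0 >= e0:
                break
            if s0 < t0 and rng.random() < site.arrest_fraction:
                s0 = t0
        bases = ref_arr[s0:e0].copy()
        # i.i.d. background miscalls
        err = rng.random(len(bases)) < spec.error_rate
        for i in np.flatnonzero(err):
            others = BASES[BASES != bases[i].decode()]
            bases[i] = rng.choice(others).encode()
        # planted misincorporation overrides
        for site in mm_sites:
            i = site.pos - 1 - s0
            if 0 <= i < len(bases) and rng.random() < site.mismatch_fraction:
                bases[i] = rng.choice(BASES, p=profiles[site.pos]).encode()
        reads.append((s0, bases.tobytes().decode("ascii")))
    return reads


def simulate_reads(spec: SimulationSpec, out_dir,
                   fasta_name: str = "reference.fa",
                   sam_name: str = "reads.sam",
                   truth_name: str = "truth.tsv") -> dict[str, Path]:
    """Generate references, reads, and the ground-truth table.

    Returns the paths of the FASTA, SAM and truth TSV written to *out_dir*.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    refs = [(f"ref{i}", generate_reference(spec.reference_length, rng))
            for i in range(1, spec.n_references + 1)]
    fasta_path = write_fasta(refs, out_dir / fasta_name)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in refs],
    })
    sam_path = out_dir / sam_name
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as fh:
        for tid, (name, seq) in enumerate(refs):
            reads = _simulate_reference_reads(spec, seq, tid + 1, rng)
            reads.sort(key=lambda r: r[0])
            for i, (s0, bases) in enumerate(reads):
                a = pysam.AlignedSegment(header)
                a.query_name = f"ref{tid + 1}_read{i:07d}"
                a.query_sequence = bases
                a.flag = 0
                a.reference_id = tid
                a.reference_start = s0
                a.mapping_quality = 60
                a.cigartuples = [(0, len(bases))]
                a.query_qualities = pysam.qualitystring_to_array("I" * len(bases))
                fh.write(a)

    truth_path = out_dir / truth_name
    with open(truth_path, "w") as fh:
        fh.write("ref_index\tpos\tmismatch_fraction\tarrest_fraction\tlabel\n")
        for s in sorted(spec.sites, key=lambda s: (s.ref_index, s.pos)):
            fh.write(f"{s.ref_index}\t{s.pos}\t{s.mismatch_fraction}"
                     f"\t{s.arrest_fraction}\t{s.label}\n")

    return {"fasta": fasta_path, "sam": sam_path, "truth": truth_path}


def read_truth(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
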