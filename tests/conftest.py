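import numpy as np
import pandas as pd
import pysam
import pytest
from Bio import SeqIO

from rtsig import ingest, profiles, simulate


def make_sam(path, reference_name, reference_length, reads):
    """Write a SAM file from (name, flag, pos1, cigar, seq) tuples."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    })
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for name, flag, pos1, cigar, seq in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            if flag & 4:
                a.reference_id, a.reference_start = -1, -1
            else:
                a.reference_id, a.reference_start = 0, pos1 - 1
                a.mapping_quality = 60
                a.cigarstring = cigar
            a.query_sequence = seq
            fh.write(a)
    return path


def random_profile(rng, n, max_cov=100, p_n_ref=0.02):
    """Random but internally consistent profile table for oracle tests."""
    cov = rng.integers(0, max_cov + 1, size=n)
    bases = np.array(list("ACGT"))
    ref = rng.choice(np.append(bases, "N"), size=n,
                     p=[(1 - p_n_ref) / 4] * 4 + [p_n_ref])
    counts = np.zeros((n, 4), dtype=int)
    for i in range(n):
        if cov[i] == 0:
            continue
        w = rng.dirichlet(np.full(4, 0.5))
        counts[i] = rng.multinomial(cov[i], w)
    arrest = np.where(cov > 0, rng.random(n), np.nan)
    df = pd.DataFrame({
        "pos": np.arange(1, n + 1),
        "ref_base": ref,
        "coverage": cov,
        "mismatch_rate": np.nan,
        "n_A": counts[:, 0], "n_G": counts[:, 2],
        "n_T": counts[:, 3], "n_C": counts[:, 1],
        "arrest_rate": arrest,
    })
    order = np.array(list("ACGT"))
    is_ref = ref[:, None] == order[None, :]
    mm = np.where(is_ref, 0, np.stack([df.n_A, df.n_C, df.n_G, df.n_T], 1)).sum(1)
    df["mismatch_rate"] = np.where((cov > 0) & np.isin(ref, order),
                                   mm / np.where(cov > 0, cov, 1), np.nan)
    return df


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """Small simulated dataset with one mismatch and one arrest site."""
    out = tmp_path_factory.mktemp("sim")
    spec = simulate.SimulationSpec(
        reference_length=3000, coverage_target=200, read_length=60,
        error_rate=0.005,
        sites=[
            simulate.PlantedSite(pos=700, mismatch_fraction=0.4,
                                 label="m1A-like"),
            simulate.PlantedSite(pos=2100, arrest_fraction=0.5, label="arrest"),
        ],
        seed=7,
    )
    paths = simulate.simulate_reads(spec, out)
    return {"spec": spec, **paths}


@pytest.fixture(scope="session")
def planted_profile(planted_dataset):
    rec = next(SeqIO.parse(planted_dataset["fasta"], "fasta"))
    pileup = ingest.pileup_from_sam(planted_dataset["sam"], rec.id, str(rec.seq))
    prof = profiles.profile_from_columns(pileup)
    return {"pileup": pileup, "profile": prof, "record": rec,
            **planted_dataset}
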