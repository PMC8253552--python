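import numpy as np
import pandas as pd
import pysam
import pytest

from rotspeaks import DataMatrix, GroupDesign, PeakSet


@pytest.fixture
def design_3v3():
    return GroupDesign(
        {"a1": "ctrl", "a2": "ctrl", "a3": "ctrl",
         "b1": "treat", "b2": "treat", "b3": "treat"}
    )


@pytest.fixture
def design_5v5():
    d = {f"a{i}": "ctrl" for i in range(1, 6)}
    d.update({f"b{i}": "treat" for i in range(1, 6)})
    return GroupDesign(d)


@pytest.fixture
def matrix_factory():
    """Build a DataMatrix from a plain array with auto-generated ids."""

    def build(values, sample_ids=None):
        values = np.asarray(values, dtype=float)
        n_feat, n_samp = values.shape
        if sample_ids is None:
            half = n_samp // 2
            sample_ids = [f"a{i + 1}" for i in range(half)] + [
                f"b{i + 1}" for i in range(n_samp - half)
            ]
        return DataMatrix(
            values=values,
            feature_ids=np.array([f"f{i}" for i in range(n_feat)], dtype=object),
            sample_ids=np.array(sample_ids, dtype=object),
        )

    return build


@pytest.fixture
def peakset_factory():
    def build(triples):
        return PeakSet(
            pd.DataFrame(triples, columns=["chrom", "start", "end"])
        )

    return build


@pytest.fixture
def bam_factory(tmp_path):
    """Write a coordinate-sorted, indexed BAM from fragment specs.

    Each spec is (chrom, start, fragment_length); two properly paired
    100 bp-or-shorter mates are emitted per fragment.
    """
    contigs = [("chr1", 1_000_000), ("chr2", 1_000_000)]

    def build(fragments, name="sample", mapq=60, read_len=None):
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in contigs],
        }
        path = tmp_path / f"{name}.bam"
        recs = []
        for i, (chrom, start, flen) in enumerate(fragments):
            rl = read_len or min(50, flen)
            tid = [c for c, _ in contigs].index(chrom)
            r1 = pysam.AlignedSegment()
            r1.query_name = f"frag{i}"
            r1.query_sequence = "A" * rl
            r1.reference_id = tid
            r1.reference_start = start
            r1.mapping_quality = mapq
            r1.cigar = [(0, rl)]
            r1.flag = 0x1 | 0x2 | 0x40 | 0x20  # paired, proper, read1, mate rev
            r1.next_reference_id = tid
            r1.next_reference_start = start + flen - rl
            r1.template_length = flen
            r1.set_tag("RG", name)
            r2 = pysam.AlignedSegment()
            r2.query_name = f"frag{i}"
            r2.query_sequence = "A" * rl
            r2.reference_id = tid
            r2.reference_start = start + flen - rl
            r2.mapping_quality = mapq
            r2.cigar = [(0, rl)]
            r2.flag = 0x1 | 0x2 | 0x80 | 0x10  # paired, proper, read2, rev
            r2.next_reference_id = tid
            r2.next_reference_start = start
            r2.template_length = -flen
            recs.extend([r1, r2])
        recs.sort(key=lambda r: (r.reference_id, r.reference_start))
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for rec in recs:
                bam.write(rec)
        pysam.index(str(path))
        return str(path)

    return build
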