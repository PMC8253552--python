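"""From per-sample peak calls and alignments to a count matrix.

Writes two small BED peak files and two synthetic paired-end BAMs into a
temporary directory, merges the peak calls into candidate peaks, counts
fragments per peak per sample, and normalizes by median of ratios.
"""

import tempfile
from pathlib import Path

import pysam

from rotspeaks import count_reads, median_of_ratios, merge_candidate_peaks, read_peaks

workdir = Path(tempfile.mkdtemp(prefix="rotspeaks_example_"))

# two samples called slightly different peaks over the same loci
(workdir / "s1.bed").write_text(
    "chr1\t1000\t1600\nchr1\t5000\t5800\nchr1\t9000\t9500\n"
)
(workdir / "s2.bed").write_text(
    "chr1\t1200\t1900\nchr1\t5100\t5900\n"
)


def write_bam(path, fragments):
    """fragments: (start, length) pairs of properly paired templates."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": 100_000}]}
    recs = []
    for i, (start, flen) in enumerate(sorted(fragments)):
        for is_read2 in (False, True):
            rec = pysam.AlignedSegment()
            rec.query_name = f"frag{i}"
            rec.query_sequence = "A" * 50
            rec.reference_id = 0
            rec.reference_start = start + (flen - 50 if is_read2 else 0)
            rec.mapping_quality = 60
            rec.cigar = [(0, 50)]
            rec.flag = (0x1 | 0x2 | 0x80 | 0x10) if is_read2 else (
                0x1 | 0x2 | 0x40 | 0x20
            )
            rec.next_reference_id = 0
            rec.next_reference_start = start + (0 if is_read2 else flen - 50)
            rec.template_length = -flen if is_read2 else flen
            recs.append(rec)
    recs.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rec in recs:
            bam.write(rec)
    pysam.index(str(path))


write_bam(workdir / "s1.bam",
          [(1100, 200), (1300, 150), (5200, 300), (9100, 180)])
write_bam(workdir / "s2.bam",
          [(1150, 250), (5300, 200), (5500, 180), (20_000, 150)])

peaks = merge_candidate_peaks(
    [read_peaks(workdir / "s1.bed"), read_peaks(workdir / "s2.bed")]
)
print("merged candidate peaks:")
print(peaks.frame.to_string(index=False))

counts = count_reads(
    peaks,
    {"s1": str(workdir / "s1.bam"), "s2": str(workdir / "s2.bam")},
    mode="fragment",
)
print("\nfragment counts per peak:")
print(counts.to_data_matrix().to_frame().to_string())

factors, normalized = median_of_ratios(counts)
print("\nsize factors:", dict(zip(counts.sample_ids, factors.round(3))))
# Overlapping per-sample peaks fuse into single candidate regions; each
# properly paired fragment increments every peak it overlaps by >= 1 bp.
# The fragment at 20 kb falls outside every candidate peak and is ignored.
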