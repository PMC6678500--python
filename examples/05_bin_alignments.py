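"""Count aligned reads from a (toy) SAM file into 20 kbp bins.

Builds a miniature two-chromosome SAM in a temporary directory, bins its
alignments with the MAPQ >= 40 filter, and aggregates to per-chromosome
counts.  Real use is identical with a coordinate-sorted BAM and the hg19
FASTA (for per-bin GC): ``bin_alignments("sample.bam", fasta_path="hg19.fa")``.
"""

import tempfile
from pathlib import Path

from adanipt import aggregate_to_chromosomes, bin_alignments

sam = ["@HD\tVN:1.6\tSO:coordinate",
       "@SQ\tSN:chr1\tLN:100000",
       "@SQ\tSN:chr2\tLN:60000"]
reads = [("chr1", 1, 60), ("chr1", 20001, 60), ("chr1", 20500, 60),
         ("chr2", 500, 60), ("chr2", 999, 39)]  # last one fails MAPQ
for i, (ref, pos, mapq) in enumerate(reads):
    sam.append(f"r{i}\t0\t{ref}\t{pos}\t{mapq}\t35M\t*\t0\t0\t" +
               "A" * 35 + "\t" + "I" * 35)

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "toy.sam"
    path.write_text("\n".join(sam) + "\n")
    matrix = bin_alignments(str(path), bin_size=20_000, mapq_min=40)

print(f"{matrix.n_bins} bins tiled over chr1 (100 kb) + chr2 (60 kb)")
print("bin counts:", matrix.counts[0].astype(int).tolist())
(per_chrom,) = aggregate_to_chromosomes(matrix)
print("reads per chromosome:", {i + 1: int(v) for i, v in
                                enumerate(per_chrom.x) if v})
print("(the MAPQ-39 read was dropped; positions 20001+ fall in chr1 bin 2)")
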