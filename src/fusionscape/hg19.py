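"""Standard hg19 (GRCh37) chromosome lengths, chr1-22, X, Y.

Embedded so the uniform breakage-and-rejoin null over the human genome can be
evaluated without any external data download.
"""

from .genome import ChromosomeTable

HG19_CHROM_SIZES: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}


def hg19_table() -> ChromosomeTable:
    return ChromosomeTable.from_mapping(HG19_CHROM_SIZES)
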