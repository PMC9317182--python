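"""hg19 (GRCh37) chromosome geometry.

All coordinates in this package are 1-based inclusive on hg19, with bare
chromosome names ("1".."22", "X", "Y").  Only the geometry needed by the
pipeline is bundled: chromosome lengths and approximate centromere midpoints
(used to place peri-centromeric masks and to explain discordant calls near
centromeres/telomeres).  No sequence is ever touched.
"""

from __future__ import annotations

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

# hg19 chromosome lengths (bp), UCSC chromInfo.
CHROM_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}

# Approximate hg19 centromere midpoints (bp), from the UCSC gap track.
CENTROMERE_MID: dict[str, int] = {
    "1": 123035434, "2": 93826171, "3": 92004854, "4": 51160117,
    "5": 47905641, "6": 60330166, "7": 59554331, "8": 45338887,
    "9": 48867679, "10": 40754935, "11": 53144205, "12": 36356694,
    "13": 17500000, "14": 17100000, "15": 18260000, "16": 38335801,
    "17": 22563133, "18": 16960898, "19": 26181782, "20": 27869569,
    "21": 12788129, "22": 14500000, "X": 60132012, "Y": 11604553,
}


def normalize_chrom(name: str) -> str:
    """Map 'chr13' / '13' / 'chrX' to the bare internal name, or raise."""
    bare = name[3:] if name.lower().startswith("chr") else name
    bare = "X" if bare in ("x", "23") else "Y" if bare in ("y", "24") else bare
    if bare not in CHROM_LENGTHS:
        raise ValueError(f"unknown chromosome name: {name!r}")
    return bare


def centromere_telomere_intervals(flank_bp: int = 3_000_000):
    """(chrom, start, end) triples covering telomeric and peri-centromeric
    windows of each chromosome; used both as the default analysis mask and as
    the annotation behind the 'centromeric/telomeric' discrepancy reason."""
    out = []
    for chrom, length in CHROM_LENGTHS.items():
        mid = CENTROMERE_MID[chrom]
        out.append((chrom, 1, min(flank_bp, length)))
        out.append((chrom, max(1, mid - flank_bp), min(length, mid + flank_bp)))
        out.append((chrom, max(1, length - flank_bp + 1), length))
    return out
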