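"""One-off generator for the packaged TSV resources.

Run from repo root: python scripts/gen_resources.py
Deterministic (fixed seed) so the committed resources are reproducible.
"""
import random
from pathlib import Path

RES = Path(__file__).resolve().parents[1] / "src" / "oamlseq" / "resources"

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# the 24-gene panel with signalling-pathway assignments
PANEL = [
    ("BCL10", "NF-kB canonical"),
    ("BIRC3", "NF-kB canonical and non-canonical"),
    ("CARD11", "NF-kB canonical"),
    ("CD79A", "NF-kB canonical"),
    ("CD79B", "NF-kB canonical"),
    ("CYLD", "NF-kB canonical and non-canonical"),
    ("FAS", "Extrinsic apoptosis"),
    ("IKBKG", "NF-kB canonical"),
    ("KMT2D", "Methylation"),
    ("MALT1", "NF-kB canonical"),
    ("MAP3K7", "NF-kB canonical"),
    ("MAP3K14", "NF-kB non-canonical"),
    ("MYD88", "NF-kB canonical"),
    ("NFKBIA", "NF-kB canonical"),
    ("NOTCH1", "Notch"),
    ("NOTCH2", "Notch"),
    ("RIPK1", "NF-kB canonical"),
    ("RIPK2", "NF-kB canonical"),
    ("TNFAIP3", "NF-kB canonical"),
    ("TNIP1", "NF-kB canonical"),
    ("TNIP2", "NF-kB canonical"),
    ("TP53", "Extrinsic apoptosis"),
    ("TRAF3", "NF-kB non-canonical"),
    ("TRAF6", "NF-kB canonical"),
]

# Approximate standard protein-annotation intervals, 1-based aa coordinates,
# restricted to the domain vocabulary used for these four genes.
DOMAINS = [
    ("NOTCH1", "EGF", 20, 1426),
    ("NOTCH1", "LNR", 1449, 1563),
    ("NOTCH1", "HD-N", 1571, 1679),
    ("NOTCH1", "HD-C", 1680, 1735),
    ("NOTCH1", "TM", 1736, 1756),
    ("NOTCH1", "RAM", 1763, 1848),
    ("NOTCH1", "ANK", 1927, 2093),
    ("NOTCH1", "NLS", 2105, 2140),
    ("NOTCH1", "TAD", 2194, 2398),
    ("NOTCH1", "PEST", 2480, 2555),
    ("NOTCH2", "EGF", 26, 1372),
    ("NOTCH2", "LNR", 1378, 1491),
    ("NOTCH2", "HD-N", 1500, 1605),
    ("NOTCH2", "HD-C", 1606, 1672),
    ("NOTCH2", "TM", 1677, 1697),
    ("NOTCH2", "RAM", 1705, 1790),
    ("NOTCH2", "ANK", 1828, 1994),
    ("NOTCH2", "TAD", 2100, 2300),
    ("NOTCH2", "PEST", 2400, 2471),
    ("KMT2D", "PHD", 150, 350),
    ("KMT2D", "HMG", 2030, 2100),
    ("KMT2D", "NLS", 3560, 3580),
    ("KMT2D", "FYRN", 4995, 5048),
    ("KMT2D", "FYRC", 5242, 5298),
    ("KMT2D", "SET", 5397, 5513),
    ("TNFAIP3", "ZNF", 381, 405),
    ("TNFAIP3", "ZNF", 472, 496),
    ("TNFAIP3", "ZNF", 514, 538),
    ("TNFAIP3", "ZNF", 587, 611),
    ("TNFAIP3", "ZNF", 639, 663),
    ("TNFAIP3", "ZNF", 685, 709),
    ("TNFAIP3", "ZNF", 755, 779),
]

# gene, chrom, genomic start of window (1-based), aa number of first codon,
# number of codons, {aa -> fixed codon}
WINDOWS = [
    ("BCL10", "chr1", 85733000, 100, 45, {}),
    ("BIRC3", "chr11", 102188000, 300, 45, {}),
    ("CARD11", "chr7", 2946000, 200, 45, {}),
    ("CD79A", "chr19", 42381000, 50, 45, {}),
    ("CD79B", "chr17", 62006000, 150, 45, {}),
    ("CYLD", "chr16", 50775000, 400, 45, {}),
    ("FAS", "chr10", 90750000, 120, 45, {}),
    ("IKBKG", "chrX", 153770000, 180, 45, {}),
    ("KMT2D", "chr12", 49420500, 5420, 45, {}),   # SET domain
    ("KMT2D", "chr12", 49425000, 2500, 60, {}),
    ("MALT1", "chr18", 56338000, 300, 45, {}),
    ("MAP3K7", "chr6", 91223000, 200, 45, {}),
    ("MAP3K14", "chr17", 43340000, 400, 45, {}),
    ("MYD88", "chr3", 38182565, 240, 60, {265: "CTG"}),  # Leu265, T at 38182641
    ("NFKBIA", "chr14", 35871000, 100, 45, {}),
    ("NOTCH1", "chr9", 139399000, 1580, 45, {}),  # HD-N
    ("NOTCH1", "chr9", 139390800, 2480, 76, {}),  # PEST, contains 139390945
    ("NOTCH2", "chr1", 120458000, 2150, 45, {}),  # TAD
    ("NOTCH2", "chr1", 120459000, 2410, 45, {}),  # PEST
    ("RIPK1", "chr6", 3064000, 250, 45, {}),
    ("RIPK2", "chr8", 90770000, 200, 45, {}),
    ("TNFAIP3", "chr6", 138192000, 280, 60, {}),
    ("TNFAIP3", "chr6", 138196000, 587, 21, {}),  # ZNF
    ("TNIP1", "chr5", 150410000, 300, 45, {}),
    ("TNIP2", "chr4", 2743000, 200, 45, {}),
    ("TP53", "chr17", 7573000, 150, 45, {}),
    ("TRAF3", "chr14", 103240000, 300, 45, {}),
    ("TRAF6", "chr11", 36510000, 250, 45, {}),
]


def main() -> None:
    rng = random.Random(1234)

    with open(RES / "panel_genes.tsv", "w") as fh:
        fh.write("gene\tpathway\n")
        for gene, pw in PANEL:
            fh.write(f"{gene}\t{pw}\n")

    with open(RES / "domains.tsv", "w") as fh:
        fh.write("gene\tdomain\taa_start\taa_end\n")
        for gene, dom, s, e in DOMAINS:
            fh.write(f"{gene}\t{dom}\t{s}\t{e}\n")

    windows = []
    for gene, chrom, start, aa_start, n_codons, fixed in WINDOWS:
        codons = []
        for i in range(n_codons):
            aa = aa_start + i
            codons.append(fixed.get(aa) or rng.choice(SENSE_CODONS))
        seq = "".join(codons)
        windows.append((gene, chrom, start, aa_start, seq))

    with open(RES / "cds_windows_synthetic.tsv", "w") as fh:
        fh.write("gene\tchrom\tstart\taa_start\tseq\n")
        for gene, chrom, start, aa_start, seq in windows:
            fh.write(f"{gene}\t{chrom}\t{start}\t{aa_start}\t{seq}\n")

    # NOTCH1 deletion hotspot at chr9:139390945 (anchor-base representation:
    # ref = bases at pos..pos+1, alt = base at pos).
    pest = next(w for w in windows if w[0] == "NOTCH1" and w[2] == 139390800)
    idx = 139390945 - pest[2]
    ref = pest[4][idx : idx + 2]
    alt = pest[4][idx]
    with open(RES / "blacklist.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tnote\n")
        fh.write(
            f"chr9\t139390945\t{ref}\t{alt}\t"
            "recurrent NOTCH1 1bp-deletion artifact not confirmed by resequencing\n"
        )
    print("MYD88 codon check:", windows and "ok")
    myd = next(w for w in windows if w[0] == "MYD88")
    assert myd[4][3 * (265 - 240) : 3 * (265 - 240) + 3] == "CTG"
    print("blacklist ref/alt:", ref, alt)


if __name__ == "__main__":
    main()
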