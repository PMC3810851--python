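import numpy as np
import pytest

from zimpute.panel import ReferencePanel


def make_panel(H, pos=None, ref=None, alt=None, chrom="1"):
    """Build a panel directly from a 0/1 haplotype matrix (rows=haplotypes)."""
    H = np.asarray(H, dtype=np.uint8)
    n = H.shape[1]
    if pos is None:
        pos = 100 * (np.arange(n) + 1)
    if ref is None:
        ref = ["A"] * n
    if alt is None:
        alt = ["G"] * n
    return ReferencePanel(
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        H=H,
    )


def write_vcf(path, rows, n_samples, phased=True, extra_header=""):
    """Write a minimal VCF. ``rows``: (chrom, pos, ref, alt, [gt strings])."""
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(extra_header)
        samples = "\t".join(f"S{i}" for i in range(n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for chrom, pos, ref, alt, gts in rows:
            gt = "\t".join(g.replace("|", sep) for g in gts)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")
    return path


@pytest.fixture
def small_panel():
    """8 haplotypes x 6 variants, all polymorphic, assorted LD."""
    rng = np.random.default_rng(11)
    H = rng.integers(0, 2, size=(8, 6))
    H[:, 1] = H[:, 0]          # perfect proxy pair (0, 1)
    H[:, 3] = 1 - H[:, 2]      # perfect anti-proxy pair (2, 3)
    for j in range(6):         # ensure polymorphic
        if H[:, j].min() == H[:, j].max():
            H[0, j] ^= 1
    return make_panel(H)
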