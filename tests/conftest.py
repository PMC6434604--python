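import numpy as np
import pytest

from edgefront.core_data import GenotypeMatrix, LocusInfo, PopulationMap


def make_gm(calls, samples=None, tags=None):
    """Build a GenotypeMatrix from a nested list of dosages (-1 = missing).

    ``tags`` optionally maps locus index -> tag id (default: one tag per
    locus).
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_loci = calls.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    loci = []
    for j in range(n_loci):
        tag = (tags or {}).get(j, f"tag{j}")
        prev = sum(1 for l in loci if l.tag_id == tag)
        loci.append(
            LocusInfo(locus_id=f"L{j}", tag_id=tag, pos=prev + 1, ref="A", alt="C")
        )
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def make_pm(assignments, coords=None):
    return PopulationMap(sample_to_pop=dict(assignments), coordinates=coords or {})


@pytest.fixture
def toy_gm_pm():
    """Two pops x three loci used by several hand-computed oracles."""
    gm = make_gm(
        [
            [0, 0, 1],
            [0, 1, 2],
            [1, 0, 0],
            [2, 1, 1],
        ]
    )
    pm = make_pm({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    return gm, pm


def write_vcf_text(path, records, samples=("s0", "s1")):
    """Write a minimal VCF with explicit record lines for parser tests."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = {r[0] for r in records}
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, vid, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
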