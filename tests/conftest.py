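"""Shared fixtures: small text fixtures and the canonical synthetic cohort."""

from __future__ import annotations

import textwrap

import pytest

from pedcascade import generate_cohort, make_family_pedigree


@pytest.fixture(scope="session")
def canonical():
    """Canonical labelled cohort at seed 1: (cohort, ground-truth fates)."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def family_pedigree():
    return make_family_pedigree()


# ---------------------------------------------------------------------------
# VCF / PED text fixtures
# ---------------------------------------------------------------------------

SAMPLES = ["I-1", "I-2", "II-1", "II-2", "II-3", "II-4", "II-5", "II-6"]

TWO_RECORD_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=6>
    ##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
    6\t144095295\t.\tG\tA\t.\tPASS\tGENE=PHACTR2\tGT\t0/1\t0/1\t0/0\t0/1\t1/1\t0/0\t0/1\t0/0
    6\t144100000\t.\tC\tT\t.\tPASS\tGENE=GENEX\tGT\t0/0\t1/0\t0/0\t./.\t0/1\t0/0\t0/0\t0/0
    """).format(samples="\t".join(SAMPLES))

MULTIALLELIC_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=1>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
    1\t1000\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\t0/1\t2/2
    """)


@pytest.fixture
def two_record_vcf(tmp_path):
    path = tmp_path / "two.vcf"
    path.write_text(TWO_RECORD_VCF)
    return path


@pytest.fixture
def multiallelic_vcf(tmp_path):
    path = tmp_path / "multi.vcf"
    path.write_text(MULTIALLELIC_VCF)
    return path


# ---------------------------------------------------------------------------
# Toy PDB builder (synthetic stand-in geometry, no real structure shipped)
# ---------------------------------------------------------------------------

def pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                  resseq: int, x: float, y: float, z: float,
                  element: str, altloc: str = " ") -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
            f"{resseq:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}"
            f"{0.0:>6.2f}          {element:>2s}")


def make_pdb(atoms: list[tuple]) -> str:
    """atoms: (name, resname, resseq, x, y, z[, element[, altloc]])."""
    lines = []
    for i, spec in enumerate(atoms, start=1):
        name, resname, resseq, x, y, z = spec[:6]
        element = spec[6] if len(spec) > 6 else name[0]
        altloc = spec[7] if len(spec) > 7 else " "
        lines.append(pdb_atom_line(i, name, resname, "A", resseq,
                                   x, y, z, element, altloc))
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def rpel_pdb(tmp_path):
    from pedcascade.synthetic_data import synthetic_rpel_end_pdb

    path = tmp_path / "rpel_end_synthetic.pdb"
    path.write_text(synthetic_rpel_end_pdb())
    return path
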