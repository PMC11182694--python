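import numpy as np
import pytest

from dtmr.sumstats import AssociationRecord, Variant


@pytest.fixture
def make_record():
    """Factory for association records with sensible defaults."""

    def _make(
        vid="rs1",
        beta=0.1,
        se=0.01,
        pvalue=None,
        trait="protein",
        chrom="1",
        pos=100,
        ea="A",
        oa="G",
        eaf=0.25,
        consequence="",
        sift="",
        polyphen="",
        n=10_000,
        unit="sd_protein",
    ):
        from scipy import stats as st

        if pvalue is None:
            pvalue = float(np.clip(2 * st.norm.sf(abs(beta / se)), 5e-324, 1.0))
        return AssociationRecord(
            variant=Variant(
                id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
                eaf=eaf, consequence=consequence, sift=sift, polyphen=polyphen,
            ),
            trait=trait,
            beta=beta,
            se=se,
            pvalue=pvalue,
            n=n,
            unit=unit,
        )

    return _make


@pytest.fixture
def sumstats_file(tmp_path):
    """Write a delimited summary-statistics file and return its path."""

    def _write(rows, header=None, sep="\t", name="sumstats.tsv"):
        header = header or [
            "id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n",
        ]
        path = tmp_path / name
        lines = [sep.join(header)]
        lines += [sep.join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
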