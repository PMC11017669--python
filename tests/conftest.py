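import numpy as np
import pytest

from mrscreen.sumstats import HarmonizedSet, SummaryStatTable, VariantRecord

NONPAL = [("A", "G"), ("T", "C"), ("C", "A"), ("G", "T")]


def make_record(
    variant_id,
    chrom="1",
    pos=None,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=1e-6,
    n=7824,
):
    if pos is None:
        pos = 1000 + abs(hash(variant_id)) % 10_000_000
    return VariantRecord(variant_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)


def make_table(records, trait_id="exp", trait_role="exposure"):
    return SummaryStatTable.from_records(trait_id, trait_role, records)


def make_harmonized(gamma, Gamma, se_x=None, se_y=None, n_exp=7824, n_out=460000):
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    k = len(gamma)
    se_x = np.full(k, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    se_y = np.full(k, 0.005) if se_y is None else np.asarray(se_y, dtype=float)
    return HarmonizedSet(
        "exp", "out", [f"rs{i+1:04d}" for i in range(k)],
        gamma, se_x, Gamma, se_y, np.full(k, 0.3), n_exp, n_out,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_gmt(tmp_path):
    """Small metabolite-set library: 10-compound background across 3 sets."""
    lines = [
        "Carnitine synthesis\tdesc\tglycine\tlysine\toxoglutaric acid",
        "Galactose metabolism\tdesc\tfructose\tmannose\tgalactose\tglucose",
        "TCA cycle\tdesc\tcitrate\toxoglutaric acid\tmalate\tfumarate",
    ]
    p = tmp_path / "lib.gmt"
    p.write_text("\n".join(lines) + "\n")
    return p
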