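import numpy as np
import pandas as pd
import pytest

from faerspv import io, synth


def write_table(path, header, rows):
    """Write a '$'-delimited table file from a header list and row lists."""
    lines = ["$".join(header)] + ["$".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def make_quarter(demo_rows, drug_rows=(), reac_rows=(), ther_rows=(), outc_rows=(),
                 indi_rows=(), quarter="2022Q1"):
    """Build a RawQuarter directly from row dicts (no file round trip)."""
    def df(rows, cols):
        return pd.DataFrame(list(rows), columns=cols, dtype=str) if rows else \
            pd.DataFrame(columns=cols, dtype=str)

    return io.RawQuarter(
        demo=df(demo_rows, ["primaryid", "caseid", "fda_dt", "event_dt", "age",
                            "age_cod", "sex", "occp_cod", "occr_country"]),
        drug=df(drug_rows, ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]),
        reac=df(reac_rows, ["primaryid", "pt"]),
        ther=df(ther_rows, ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"]),
        outc=df(outc_rows, ["primaryid", "outc_cod"]),
        indi=df(indi_rows, ["primaryid", "indi_drug_seq", "indi_pt"]),
        quarter=quarter,
    )


def demo_row(pid, caseid, fda="20220115", event="", age="40", unit="YR", sex="F",
             occ="MD", country="US"):
    return [pid, caseid, fda, event, age, unit, sex, occ, country]


@pytest.fixture(scope="session")
def spiked_dataset():
    """Mid-size synthetic dataset with one RR-spiked PT (keratitis, RR 8)."""
    cfg = synth.SyntheticConfig(n_cases=20000, target_rr={"keratitis": 8.0}, seed=11)
    return synth.generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_tables(rng, n, lo=1, hi=500):
    """Random strictly positive 2x2 tables for oracle-equivalence checks."""
    cells = rng.integers(lo, hi, size=(n, 4))
    from faerspv.signals import ContingencyTable
    return [ContingencyTable(*map(float, row)) for row in cells]
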