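import pandas as pd
import pytest

from faers_forge.synthetic import (SynthConfig, build_mini_vocabulary,
                                   generate_dataset)


@pytest.fixture(scope="session")
def mini():
    return build_mini_vocabulary()


@pytest.fixture(scope="session")
def small_run(mini):
    """A mid-sized generated dataset with duplicates, shared across tests."""
    cfg = SynthConfig(n_cases=2000, seed=7, duplicate_rate=0.2)
    ds, ledger, _ = generate_dataset(cfg, mini)
    return cfg, ds, ledger


def write_quarter(tmpdir, period, tables):
    """Write raw "$"-delimited quarter files; tables: kind -> (header, rows)."""
    from faers_forge.report_io import QuarterExtract
    qdir = tmpdir / period
    qdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, (header, rows) in tables.items():
        path = qdir / f"{kind.upper()}{period}.txt"
        lines = ["$".join(header)] + ["$".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        paths[kind] = path
    return QuarterExtract(period=period, paths=paths)


def norm_frame(df: pd.DataFrame) -> pd.DataFrame:
    """String-normalize a table for exact comparisons across IO paths."""
    return df.astype(object).where(df.notna(), "").astype(str)
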