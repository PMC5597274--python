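"""CSV/TSV helpers that stamp run metadata into a comment header."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None, sep: str = ","
) -> None:
    """Write ``df`` with '# key=value' comment lines ahead of the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def read_meta(path: str | Path) -> dict:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
    return meta
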