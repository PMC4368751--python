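"""Tab-separated input/output for expression, clinical and signature files.

Formats:

* expression: genes x samples TSV, first column gene identifiers, header
  row of sample identifiers;
* clinical: TSV with columns ``sample_id``, ``time``, ``event`` and any
  further covariate columns;
* signature: two-column TSV ``gene``, ``sign`` with sign in {+, -}.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ParseError
from .signature import Signature
from .survival import SurvivalCohort


def read_expression(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][:5].tolist()
        raise ParseError(f"{path}: duplicate gene identifiers, e.g. {dup}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric sample column(s) {non_numeric[:5]}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> SurvivalCohort:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    try:
        return SurvivalCohort(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_clinical(cohort: SurvivalCohort, path: str | Path) -> None:
    cohort.data.to_csv(path, sep="\t", index_label="sample_id")


def read_signature(path: str | Path) -> Signature:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "sign" not in cols:
        raise ParseError(f"{path}: expected columns 'gene' and 'sign'")
    signs = df[cols["sign"]].str.strip()
    bad = ~signs.isin(["+", "-"])
    if bad.any():
        raise ParseError(
            f"{path}: sign column must be '+' or '-', found "
            f"{signs[bad].unique()[:5].tolist()}"
        )
    genes = df[cols["gene"]].str.strip()
    return Signature(
        positive_genes=tuple(genes[signs == "+"]),
        negative_genes=tuple(genes[signs == "-"]),
        provenance={"source": str(path)},
    )


def write_signature(sig: Signature, path: str | Path) -> None:
    sig.to_frame().to_csv(path, sep="\t", index=False)
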