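"""Readers and writers for the pipeline's tab-separated interchange files.

Matrix files have a header row of sample ids and a first column of row
ids. Sample group labels come from a two-column samples file
(sample<TAB>group[<TAB>pair]) or from a ``_T``/``_N`` suffix
convention. All readers accept gzip-compressed input and CRLF line
endings.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import NORMAL, TUMOR, OmicsMatrix
from .preprocess import GeneModel, ProbeAnnotation

_FLOAT_FMT = "%.6g"


def write_matrix(m: OmicsMatrix, path: str | Path, label: str = "id") -> None:
    m.values.to_csv(path, sep="\t", index_label=label, float_format=_FLOAT_FMT)


def write_samples(m: OmicsMatrix, path: str | Path) -> None:
    df = pd.DataFrame({"sample": list(m.samples), "group": [m.groups[s] for s in m.samples]})
    if m.pairs is not None:
        df["pair"] = [m.pairs[s] for s in m.samples]
    df.to_csv(path, sep="\t", index=False)


def read_matrix(
    path: str | Path, samples_path: str | Path | None = None
) -> OmicsMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    pairs = None
    if samples_path is not None:
        s = pd.read_csv(samples_path, sep="\t")
        groups = pd.Series(s["group"].to_numpy(), index=s["sample"])
        if "pair" in s.columns:
            pairs = pd.Series(s["pair"].to_numpy(), index=s["sample"])
    else:  # suffix convention: *_T tumor, *_N normal
        groups = {}
        for col in values.columns:
            if col.endswith("_T"):
                groups[col] = TUMOR
            elif col.endswith("_N"):
                groups[col] = NORMAL
            else:
                raise ValueError(
                    f"sample {col!r}: no samples file and no _T/_N suffix"
                )
        groups = pd.Series(groups)
    return OmicsMatrix(values, groups, pairs)


def write_gene_models(models: list[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chromosome, g.tss, g.strand) for g in models],
        columns=["gene_id", "chromosome", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r.gene_id), str(r.chromosome), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_probe_annotation(ann: dict[str, ProbeAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.probe_id, a.chromosome, a.position) for a in ann.values()],
        columns=["probe_id", "chromosome", "position"],
    ).to_csv(path, sep="\t", index=False)


def read_probe_annotation(path: str | Path) -> dict[str, ProbeAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.probe_id): ProbeAnnotation(str(r.probe_id), str(r.chromosome), int(r.position))
        for r in df.itertuples()
    }


def write_edge_list(net, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


def write_truth_labels(labels, path: str | Path) -> None:
    rows = [
        (g, cls, int(g in labels.driver_genes))
        for g, cls in sorted(labels.gene_class.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "class", "driver"]).to_csv(
        path, sep="\t", index=False
    )


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
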