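"""Tabular input/output for the quantification pipeline.

Three text formats are understood:

* spectral-count matrices — TSV, first column the protein identifier,
  a ``mw_da`` and/or ``length_aa`` column, remaining columns integer
  spectral counts, one column per replicate sample;
* GMT annotation sets — ``term_id<TAB>term_name<TAB>member...``;
* transcriptome fold-change tables — TSV with ``gene_id`` and
  ``mrna_log2fc`` columns (log2 fold change, first condition over second).

Sample-to-condition assignment is always supplied explicitly (a mapping or
a small YAML file), never inferred from sample names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "SpectralCountMatrix",
    "AnnotationSets",
    "read_counts",
    "read_condition_map",
    "read_gmt",
    "read_transcriptome",
    "write_table",
    "read_table",
]

#: Reserved (non-sample) column names in a count matrix file.
METADATA_COLUMNS = ("mw_da", "length_aa")


class FormatError(ValueError):
    """Raised when an input file or in-memory table violates the format contract."""


@dataclass
class SpectralCountMatrix:
    """Raw spectral counts per protein per replicate sample.

    Parameters
    ----------
    counts
        Integer DataFrame, index = unique protein identifiers, columns =
        sample names. Values are raw MS/MS spectral counts (>= 0).
    conditions
        Mapping sample name -> condition label. Exactly two condition
        labels must occur; each needs at least two replicate samples.
    mw_da
        Optional molecular weight per protein in Daltons (> 0).
    length_aa
        Optional sequence length per protein in residues (> 0). At least
        one of ``mw_da`` / ``length_aa`` must be available for every
        protein; an explicit length takes precedence over one estimated
        from molecular weight.
    """

    counts: pd.DataFrame
    conditions: dict[str, str] = field(repr=False)
    mw_da: pd.Series | None = None
    length_aa: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein id(s): {dupes}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            # accept float columns only when they are exact integers
            if not np.all(np.isfinite(vals)) or not np.all(vals == np.floor(vals)):
                bad = list(zip(*np.where(~(vals == np.floor(vals)))))[:1]
                raise FormatError(f"non-integer spectral count at (row, col) {bad}")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            r, c = next(zip(*np.where(vals < 0)))
            raise FormatError(
                f"negative spectral count for protein {idx[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        missing = [s for s in self.counts.columns if s not in self.conditions]
        if missing:
            raise FormatError(f"sample(s) without condition assignment: {missing}")
        labels = sorted({self.conditions[s] for s in self.counts.columns})
        if len(labels) != 2:
            raise FormatError(
                f"exactly two condition labels required, got {labels}"
            )
        for lab in labels:
            n = sum(1 for s in self.counts.columns if self.conditions[s] == lab)
            if n < 2:
                raise FormatError(f"condition {lab!r} has {n} replicate(s); need >= 2")
        if self.mw_da is not None:
            self.mw_da = self.mw_da.reindex(idx).astype(float)
            known = self.mw_da.dropna()
            if (known <= 0).any():
                raise FormatError("molecular weights must be positive")
        if self.length_aa is not None:
            self.length_aa = self.length_aa.reindex(idx).astype(float)
            known = self.length_aa.dropna()
            if (known <= 0).any():
                raise FormatError("sequence lengths must be positive")
        has_mw = self.mw_da.notna() if self.mw_da is not None else pd.Series(False, index=idx)
        has_len = (
            self.length_aa.notna() if self.length_aa is not None else pd.Series(False, index=idx)
        )
        orphans = idx[~(has_mw | has_len)].tolist()
        if orphans:
            raise FormatError(
                f"protein(s) with neither molecular weight nor length: {orphans[:5]}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_names(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def condition_labels(self) -> tuple[str, str]:
        """The two condition labels, in order of first appearance across samples."""
        seen: list[str] = []
        for s in self.counts.columns:
            lab = self.conditions[s]
            if lab not in seen:
                seen.append(lab)
        return seen[0], seen[1]

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.counts.columns if self.conditions[s] == condition]
        if not out:
            raise KeyError(f"unknown condition {condition!r}")
        return out


@dataclass
class AnnotationSets:
    """Protein/gene annotation sets (GO terms, KEGG pathways, ...).

    ``members[term_id]`` is the non-empty set of member identifiers;
    ``names[term_id]`` a human-readable description.
    """

    members: dict[str, frozenset[str]]
    names: dict[str, str]

    def __post_init__(self) -> None:
        for tid, mem in self.members.items():
            if not mem:
                raise FormatError(f"annotation term {tid!r} has no members")

    @property
    def term_ids(self) -> list[str]:
        return list(self.members)


def read_condition_map(path: str) -> dict[str, str]:
    """Read a sample -> condition mapping from a flat YAML file."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise FormatError(f"{path}: expected a flat sample->condition mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_counts(path: str, condition_map: dict[str, str]) -> SpectralCountMatrix:
    """Read a tab-separated spectral-count file into a validated matrix.

    The first column holds protein identifiers; ``mw_da`` and/or
    ``length_aa`` columns hold per-protein metadata; every remaining
    column is one sample and must appear in ``condition_map``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    mw = df.pop("mw_da") if "mw_da" in df.columns else None
    length = df.pop("length_aa") if "length_aa" in df.columns else None
    if mw is None and length is None:
        raise FormatError(f"{path}: neither 'mw_da' nor 'length_aa' column present")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise FormatError(f"{path}: non-numeric count at protein {row!r}, sample {col!r}")
        df[col] = bad
    return SpectralCountMatrix(counts=df, conditions=condition_map, mw_da=mw, length_aa=length)


def read_gmt(path: str) -> AnnotationSets:
    """Read GMT-dialect annotation sets: ``term_id TAB term_name TAB member...``."""
    members: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'term_id<TAB>term_name<TAB>member...', "
                    f"got {len(parts)} field(s)"
                )
            tid, tname, *mem = parts
            mem = [m for m in mem if m]
            if not mem:
                raise FormatError(f"{path}:{lineno}: term {tid!r} has an empty member list")
            if tid in members:
                raise FormatError(f"{path}:{lineno}: duplicate term id {tid!r}")
            members[tid] = frozenset(mem)
            names[tid] = tname
    return AnnotationSets(members=members, names=names)


def read_transcriptome(path: str) -> pd.DataFrame:
    """Read a transcriptome fold-change table (gene_id, mrna_log2fc)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "mrna_log2fc" not in df.columns:
        raise FormatError(f"{path}: need columns 'gene_id' and 'mrna_log2fc'")
    df["gene_id"] = df["gene_id"].astype(str)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if not np.isfinite(df["mrna_log2fc"].to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite mRNA log2 fold change")
    return df.set_index("gene_id")


def write_table(df: pd.DataFrame, path: str, index_label: str | None = None) -> None:
    """Write a result table as TSV with a header row and stable column order."""
    df.to_csv(path, sep="\t", index=df.index.name is not None or index_label is not None,
              index_label=index_label)


def read_table(path: str, index_col: str | None = None) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def convert_gpm_counts(path: str) -> SpectralCountMatrix:
    """Placeholder for a search-engine (GPM/X!Tandem merged output) converter.

    Quantification here starts from protein-level spectral counts; the
    database search that produces them is an external step. A converter
    feeding this pipeline must emit the count-matrix layout
    :func:`read_counts` expects: first column the protein identifier, a
    ``mw_da`` and/or ``length_aa`` column, then one integer spectral-count
    column per run.
    """
    raise NotImplementedError(
        "search-engine output conversion is out of scope; export protein-level "
        "spectral counts as TSV (protein id, mw_da/length_aa, one column per run) "
        "and use read_counts"
    )
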