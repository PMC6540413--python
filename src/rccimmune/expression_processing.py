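"""NanoString count processing and RNA-seq unit conversions.

Implements the preprocessing chain for nCounter-style immune panel data:
background flooring against spiked-in negative controls, positive-control
scaling, log2 transform with quantile normalization, plus the FPKM/TPM unit
conversions used for RNA-seq validation cohorts.

Matrices are oriented genes (probes) as rows, samples as columns throughout.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rccimmune")

CLASS_ENDOGENOUS = "Endogenous"
CLASS_HOUSEKEEPING = "Housekeeping"
CLASS_POSITIVE = "Positive"
CLASS_NEGATIVE = "Negative"
PROBE_CLASSES = (CLASS_ENDOGENOUS, CLASS_HOUSEKEEPING, CLASS_POSITIVE, CLASS_NEGATIVE)


class ProcessingError(ValueError):
    """Raised when a processing precondition is violated."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class RawCountMatrix:
    """Probe x sample count matrix with per-probe code classes.

    Parameters
    ----------
    counts
        DataFrame indexed by unique probe names, one column per sample,
        non-negative values.
    code_class
        Series mapping probe name -> one of Endogenous / Housekeeping /
        Positive / Negative, aligned with ``counts.index``.
    """

    counts: pd.DataFrame
    code_class: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ProcessingError("probe names must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ProcessingError("counts must be non-negative")
        self.code_class = self.code_class.reindex(self.counts.index)
        if self.code_class.isna().any():
            missing = list(self.counts.index[self.code_class.isna()])[:5]
            raise ProcessingError(f"probes without a code class: {missing}")
        bad = set(self.code_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ProcessingError(f"unknown probe classes: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def probes_of(self, code_class: str) -> pd.Index:
        return self.counts.index[self.code_class == code_class]

    def gene_counts(self) -> pd.DataFrame:
        """Endogenous + housekeeping rows only (the biological gene space)."""
        keep = self.code_class.isin([CLASS_ENDOGENOUS, CLASS_HOUSEKEEPING])
        return self.counts.loc[keep]


@dataclass
class NormalizedLog2Matrix:
    """Gene x sample log2 expression with processing provenance flags."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def background_floored(self) -> bool:
        return bool(self.provenance.get("background_floored", False))

    @property
    def positive_normalized(self) -> bool:
        return bool(self.provenance.get("positive_normalized", False))

    @property
    def quantile_normalized(self) -> bool:
        return bool(self.provenance.get("quantile_normalized", False))


@dataclass
class UnitMatrix:
    """Gene x sample expression matrix with an explicit unit tag.

    unit is one of ``FPKM``, ``TPM`` or ``log2FPKM``. ``gene_lengths`` (bp)
    is carried when the unit is length-bearing; ``log2_offset`` records the
    pseudo-value added before the log transform.
    """

    values: pd.DataFrame
    unit: str
    gene_lengths: pd.Series | None = None
    log2_offset: float | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "TPM", "log2FPKM"):
            raise ProcessingError(f"unknown unit {self.unit!r}")


# ---------------------------------------------------------------------------
# NanoString processing
# ---------------------------------------------------------------------------


def background_floor(raw: RawCountMatrix) -> RawCountMatrix:
    """Floor sub-background signals at the mean negative-control count.

    Per sample, the detection limit is ``mean + 2*SD`` (sample SD, ddof=1) of
    the negative-control probes. Every endogenous/housekeeping count below the
    limit is replaced by the negative-control mean; control probes are left
    untouched.
    """
    neg = raw.counts.loc[raw.probes_of(CLASS_NEGATIVE)]
    if neg.shape[0] < 2:
        raise ProcessingError(
            "background flooring requires >=2 Negative probes to define an SD; "
            f"found {neg.shape[0]}"
        )
    m = neg.mean(axis=0)
    s = neg.std(axis=0, ddof=1)
    threshold = m + 2.0 * s

    out = raw.counts.copy()
    bio = raw.code_class.isin([CLASS_ENDOGENOUS, CLASS_HOUSEKEEPING]).to_numpy()
    arr = out.loc[bio].to_numpy(dtype=float)
    thr = threshold.to_numpy()
    bg = m.to_numpy()
    below = arr < thr[np.newaxis, :]
    arr[below] = np.broadcast_to(bg, arr.shape)[below]
    out.loc[bio] = arr

    prov = dict(raw.provenance)
    prov["background_floored"] = True
    prov.setdefault("order", []).append("background_floor")
    prov["order"] = list(prov["order"])
    return RawCountMatrix(out, raw.code_class.copy(), prov)


def _geomean(values: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(values), axis=0))


def positive_control_normalize(
    raw: RawCountMatrix, pseudo_count: float = 0.0
) -> tuple[RawCountMatrix, pd.Series]:
    """Scale each sample by its positive-control normalization factor.

    The factor for sample j is the cohort mean of per-sample geometric means
    of positive-control counts divided by sample j's own geometric mean, the
    platform's conventional scheme. Only endogenous/housekeeping counts are
    scaled. Returns the scaled matrix and the per-sample factors.

    A zero positive-control count makes the geometric mean zero; pass
    ``pseudo_count > 0`` to add a documented pseudo-count escape hatch
    (off by default).
    """
    pos = raw.counts.loc[raw.probes_of(CLASS_POSITIVE)]
    if pos.shape[0] < 1:
        raise ProcessingError("positive-control normalization requires >=1 Positive probe")
    values = pos.to_numpy(dtype=float) + pseudo_count
    if (values <= 0).any():
        raise ProcessingError(
            "zero positive-control count encountered; pass pseudo_count>0 to proceed"
        )
    geomeans = _geomean(values)
    factors = pd.Series(geomeans.mean() / geomeans, index=raw.counts.columns, name="factor")

    out = raw.counts.copy()
    bio = raw.code_class.isin([CLASS_ENDOGENOUS, CLASS_HOUSEKEEPING])
    out.loc[bio] = out.loc[bio].mul(factors, axis=1)

    prov = dict(raw.provenance)
    prov["positive_normalized"] = True
    prov["order"] = list(prov.get("order", [])) + ["positive_control_normalize"]
    return RawCountMatrix(out, raw.code_class.copy(), prov), factors


def quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Classical quantile normalization across columns.

    Each column's rank-r value is replaced by the mean over columns of the
    r-th order statistics. Tied values within a column receive the mean of
    the normalized values of their tied ranks, which makes the result
    deterministic and equivariant under row permutation.
    """
    arr = frame.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    reference = np.sort(arr, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        assigned = np.empty(arr.shape[0])
        assigned[order[:, j]] = reference
        out[:, j] = assigned
    result = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    # tie rule: average the assigned reference values over equal input values
    for j, col in enumerate(frame.columns):
        col_in = frame[col]
        if col_in.duplicated().any():
            result[col] = result[col].groupby(col_in, sort=False).transform("mean")
    return result


def log2_quantile_normalize(
    raw: RawCountMatrix, offset: float = 0.0
) -> NormalizedLog2Matrix:
    """log2-transform gene counts, then quantile-normalize across samples.

    Only endogenous + housekeeping probes are retained in the output gene
    space. Values must be strictly positive (background flooring guarantees
    this when negative controls have nonzero mean) unless ``offset`` > 0.
    """
    genes = raw.gene_counts().astype(float) + offset
    if (genes.to_numpy() <= 0).any():
        raise ProcessingError(
            "nonpositive values cannot be log2-transformed; "
            "floor the background first or pass a positive offset"
        )
    logged = np.log2(genes)
    normalized = quantile_normalize(logged)
    prov = dict(raw.provenance)
    prov["quantile_normalized"] = True
    prov["log2_offset"] = offset
    prov["order"] = list(prov.get("order", [])) + ["log2", "quantile_normalize"]
    return NormalizedLog2Matrix(normalized, prov)


# ---------------------------------------------------------------------------
# RNA-seq unit conversions
# ---------------------------------------------------------------------------


def counts_to_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> UnitMatrix:
    """Fragments per kilobase per million mapped fragments.

    fpkm_gj = counts_gj * 1e9 / (length_g * total_counts_j)
    """
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise ProcessingError(f"missing gene lengths for: {sorted(missing)}")
    lengths = lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        raise ProcessingError("gene lengths must be positive")
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ProcessingError("every sample must have a positive total count")
    fpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return UnitMatrix(fpkm, unit="FPKM", gene_lengths=lengths)


def fpkm_to_tpm(fpkm: UnitMatrix) -> UnitMatrix:
    """Rescale FPKM so every sample sums to one million (TPM)."""
    if fpkm.unit != "FPKM":
        raise ProcessingError(f"expected FPKM input, got {fpkm.unit}")
    colsums = fpkm.values.sum(axis=0)
    if (colsums <= 0).any():
        raise ProcessingError("all-zero sample column; TPM undefined")
    tpm = fpkm.values.div(colsums, axis=1) * 1e6
    return UnitMatrix(tpm, unit="TPM", gene_lengths=fpkm.gene_lengths)


def log2_fpkm(fpkm: UnitMatrix, offset: float = 1.0) -> UnitMatrix:
    """Elementwise log2(x + offset); the offset is recorded on the result."""
    if fpkm.unit != "FPKM":
        raise ProcessingError(f"expected FPKM input, got {fpkm.unit}")
    if offset < 0:
        raise ProcessingError("offset must be >= 0")
    if offset == 0 and (fpkm.values.to_numpy() == 0).any():
        raise ProcessingError("offset=0 with zero FPKM values present")
    return UnitMatrix(
        np.log2(fpkm.values + offset),
        unit="log2FPKM",
        gene_lengths=fpkm.gene_lengths,
        log2_offset=offset,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_rcc_dir(path: str) -> RawCountMatrix:
    """Read a directory of per-sample RCC-dialect files into one matrix.

    Each file carries <Header>, <Sample_Attributes>, <Lane_Attributes> and a
    <Code_Summary> section with CodeClass,Name,Accession,Count rows. Extra
    header keys are tolerated. The sample ID comes from the Sample_Attributes
    ID field, falling back to the file name.
    """
    files = sorted(
        f for f in os.listdir(path) if f.lower().endswith((".rcc", ".txt"))
    )
    if not files:
        raise ProcessingError(f"no RCC files found in {path!r}")
    per_sample: dict[str, pd.Series] = {}
    classes: pd.Series | None = None
    for fname in files:
        sample_id, table = _read_rcc_file(os.path.join(path, fname))
        if sample_id is None:
            sample_id = os.path.splitext(fname)[0]
        per_sample[sample_id] = table["Count"]
        cls = table["CodeClass"]
        if classes is None:
            classes = cls
        elif not classes.equals(cls.reindex(classes.index)):
            raise ProcessingError(f"probe annotation differs in {fname!r}")
    counts = pd.DataFrame(per_sample)
    return RawCountMatrix(counts, classes.copy())


def _read_rcc_file(fpath: str) -> tuple[str | None, pd.DataFrame]:
    section = None
    sample_id = None
    code_lines: list[str] = []
    with open(fpath) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("<") and line.endswith(">"):
                section = line.strip("<>").rstrip("/")
                continue
            if section == "Sample_Attributes":
                key, _, value = line.partition(",")
                if key == "ID":
                    sample_id = value
            elif section == "Code_Summary":
                code_lines.append(line)
    if not code_lines:
        raise ProcessingError(f"{fpath!r} has no Code_Summary section")
    table = pd.read_csv(io.StringIO("\n".join(code_lines)))
    table["Count"] = table["Count"].astype(float)
    return sample_id, table.set_index("Name")


def write_rcc_dir(raw: RawCountMatrix, path: str, accession: str = "NA") -> list[str]:
    """Write one RCC-dialect file per sample; returns the file paths."""
    os.makedirs(path, exist_ok=True)
    written = []
    for lane, sample in enumerate(raw.samples, start=1):
        fpath = os.path.join(path, f"{sample}.RCC")
        with open(fpath, "w") as fh:
            fh.write("<Header>\nFileVersion,1.7\nSoftwareVersion,rccimmune\n</Header>\n")
            fh.write(f"<Sample_Attributes>\nID,{sample}\nOwner,\nComments,\n</Sample_Attributes>\n")
            fh.write(f"<Lane_Attributes>\nID,{lane}\n</Lane_Attributes>\n")
            fh.write("<Code_Summary>\nCodeClass,Name,Accession,Count\n")
            for probe in raw.counts.index:
                fh.write(
                    f"{raw.code_class[probe]},{probe},{accession},"
                    f"{raw.counts.at[probe, sample]:g}\n"
                )
            fh.write("</Code_Summary>\n")
        written.append(fpath)
    return written


def read_counts_tsv(path: str) -> RawCountMatrix:
    """Read a combined TSV with leading CodeClass and Name columns."""
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("CodeClass", "Name"):
        if col not in table.columns:
            raise ProcessingError(f"combined TSV must have a {col!r} column")
    table = table.set_index("Name")
    classes = table.pop("CodeClass")
    return RawCountMatrix(table.astype(float), classes)


def write_counts_tsv(raw: RawCountMatrix, path: str) -> None:
    table = raw.counts.copy()
    table.insert(0, "CodeClass", raw.code_class)
    table.index.name = "Name"
    table.to_csv(path, sep="\t")


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Plain gene x sample TSV (first column gene names), '#' comments allowed."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return frame.astype(float)


def write_matrix_tsv(values: pd.DataFrame, path: str, provenance: dict | None = None) -> None:
    """Write a matrix as TSV with '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        values.to_csv(fh, sep="\t")
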