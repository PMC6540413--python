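"""Gene-set registry and signature scoring.

Deconvolution-by-signature: relative immune cell-type abundance is estimated
as the mean log2 expression of a predefined marker-gene set. The registry
holds the 24 immune cell-type signatures, the 4 immune response categories
(Adaptive, Innate, Inflammation, Humoral) and an effector-T-cell (Teff)
signature. Also implements the cytolytic activity score (CYT) and the
Teff/Treg ratio.

ESTIMATE ImmuneScore/StromalScore are deliberately not re-implemented here;
callers wanting them should adapt an external implementation to the score
table interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_processing import NormalizedLog2Matrix, UnitMatrix

logger = logging.getLogger("rccimmune")

KIND_CELL_TYPE = "cell_type"
KIND_CATEGORY = "response_category"
KIND_TEFF = "teff"
SIGNATURE_KINDS = (KIND_CELL_TYPE, KIND_CATEGORY, KIND_TEFF)

PLATFORM_NANOSTRING = "nanostring_log2"
PLATFORM_FPKM = "fpkm_log2"

#: coverage (fraction of signature genes present) below which a warning fires
DEFAULT_COVERAGE_WARN = 0.5


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: frozenset[str]
    kind: str = KIND_CELL_TYPE

    def __post_init__(self) -> None:
        if not self.genes:
            raise SignatureError(f"signature {self.name!r} has an empty gene set")
        if self.kind not in SIGNATURE_KINDS:
            raise SignatureError(f"unknown signature kind {self.kind!r}")


class SignatureRegistry:
    """Named gene sets with unique names; loadable from / writable to GMT."""

    def __init__(self, signatures: list[GeneSignature] | None = None):
        self._sigs: dict[str, GeneSignature] = {}
        for sig in signatures or []:
            self.add(sig)

    def add(self, sig: GeneSignature) -> None:
        if sig.name in self._sigs:
            raise SignatureError(f"duplicate signature name {sig.name!r}")
        self._sigs[sig.name] = sig

    def __getitem__(self, name: str) -> GeneSignature:
        return self._sigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sigs

    def __iter__(self):
        return iter(self._sigs.values())

    def __len__(self) -> int:
        return len(self._sigs)

    @property
    def names(self) -> list[str]:
        return list(self._sigs)

    def of_kind(self, kind: str) -> list[GeneSignature]:
        return [s for s in self._sigs.values() if s.kind == kind]

    # GMT: one line per set -- name, description, then tab-separated genes.
    # The description slot carries the signature kind so a round trip is
    # lossless; foreign GMTs with other descriptions load as cell_type.
    @classmethod
    def from_gmt(cls, path: str) -> "SignatureRegistry":
        reg = cls()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
                kind = desc if desc in SIGNATURE_KINDS else KIND_CELL_TYPE
                reg.add(GeneSignature(name, frozenset(genes), kind))
        return reg

    def to_gmt(self, path: str) -> None:
        with open(path, "w") as fh:
            for sig in self._sigs.values():
                genes = "\t".join(sorted(sig.genes))
                fh.write(f"{sig.name}\t{sig.kind}\t{genes}\n")


@dataclass
class SignatureScoreTable:
    """Per-sample per-signature scores (samples as rows).

    ``scale`` tags whether scores live on the log2 or linear scale;
    ``coverage`` is the per-signature fraction of its genes found in the
    expression matrix.
    """

    scores: pd.DataFrame
    scale: str = "log2"
    coverage: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# scale: {self.scale}\n")
            cov = ", ".join(f"{k}={v:.3f}" for k, v in self.coverage.items())
            fh.write(f"# coverage: {cov}\n")
            self.scores.to_csv(fh, sep="\t")


@dataclass
class TeffTregRatio:
    ratio: pd.Series
    platform: str


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, NormalizedLog2Matrix):
        return matrix.values
    if isinstance(matrix, UnitMatrix):
        if matrix.unit != "log2FPKM":
            raise SignatureError(
                f"signature scoring expects log2-scale input, got unit {matrix.unit}"
            )
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise SignatureError(f"unsupported matrix type {type(matrix).__name__}")


def score_signature(
    matrix, sig: GeneSignature, coverage_warn: float = DEFAULT_COVERAGE_WARN
) -> pd.Series:
    """Mean log2 expression of the signature's genes, per sample.

    Genes absent from the matrix are dropped (warned); a signature with no
    genes present is an error. A singleton signature's score is simply that
    gene's expression — the Treg/FOXP3 case.
    """
    frame = _as_frame(matrix)
    present = sorted(sig.genes & set(frame.index))
    if not present:
        raise SignatureError(f"no genes of signature {sig.name!r} present in matrix")
    missing = sorted(sig.genes - set(present))
    coverage = len(present) / len(sig.genes)
    if missing:
        logger.warning("signature %s: %d genes missing: %s", sig.name, len(missing), missing[:8])
    if coverage < coverage_warn:
        logger.warning("signature %s coverage %.2f below %.2f", sig.name, coverage, coverage_warn)
    scores = frame.loc[present].mean(axis=0)
    scores.name = sig.name
    return scores


def score_signatures(
    matrix, registry: SignatureRegistry, kinds: tuple[str, ...] = SIGNATURE_KINDS
) -> SignatureScoreTable:
    """Score every registry signature of the requested kinds."""
    frame = _as_frame(matrix)
    gene_space = set(frame.index)
    cols: dict[str, pd.Series] = {}
    coverage: dict[str, float] = {}
    for sig in registry:
        if sig.kind not in kinds:
            continue
        cols[sig.name] = score_signature(matrix, sig)
        coverage[sig.name] = len(sig.genes & gene_space) / len(sig.genes)
    table = pd.DataFrame(cols)
    return SignatureScoreTable(table, scale="log2", coverage=pd.Series(coverage))


def cyt_score(tpm: UnitMatrix, offset: float = 0.01) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 TPM (0.01 offset).

    CYT_j = sqrt((GZMA_j + offset) * (PRF1_j + offset))
    """
    if tpm.unit != "TPM":
        raise SignatureError(f"CYT is defined on TPM, got {tpm.unit}")
    for gene in ("GZMA", "PRF1"):
        if gene not in tpm.values.index:
            raise SignatureError(f"CYT requires gene {gene} in the matrix")
    gzma = tpm.values.loc["GZMA"] + offset
    prf1 = tpm.values.loc["PRF1"] + offset
    cyt = np.sqrt(gzma * prf1)
    cyt.name = "CYT"
    return cyt


def teff_score(matrix, teff_sig: GeneSignature) -> pd.Series:
    """Effector-T-cell score: mean expression of the Teff signature genes."""
    if teff_sig.kind != KIND_TEFF:
        raise SignatureError(f"{teff_sig.name!r} is not a teff signature")
    return score_signature(matrix, teff_sig)


def teff_treg_ratio(teff: pd.Series, treg: pd.Series, platform: str) -> TeffTregRatio:
    """Teff/Treg ratio; the transform depends on the platform.

    nanostring_log2 divides the log2-scale scores directly; fpkm_log2 first
    anti-logs both scores (so the ratio is 2**(teff - treg)). A zero Treg
    denominator on the NanoString platform yields a missing value with a
    warning rather than an error.
    """
    teff, treg = teff.align(treg, join="inner")
    if platform == PLATFORM_NANOSTRING:
        zero = treg == 0
        if zero.any():
            logger.warning(
                "Teff/Treg ratio undefined for %d sample(s) with zero Treg score", int(zero.sum())
            )
        ratio = teff / treg.where(~zero)
    elif platform == PLATFORM_FPKM:
        ratio = np.power(2.0, teff - treg)
    else:
        raise SignatureError(f"unknown platform {platform!r}")
    ratio.name = "Teff_Treg_ratio"
    return TeffTregRatio(ratio, platform)


def standardize_scores(table: SignatureScoreTable) -> pd.DataFrame:
    """Z-standardize each signature column (sample SD, ddof=1)."""
    scores = table.scores
    if scores.shape[0] < 2:
        raise SignatureError("standardization requires >=2 samples")
    sd = scores.std(axis=0, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise SignatureError(f"zero-variance signature(s): {list(flat.index)}")
    return (scores - scores.mean(axis=0)) / sd
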