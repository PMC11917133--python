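"""Reading, writing and site-level filtering of the pipeline's file formats.

The pipeline's universal input is a :class:`VariantTable`: biallelic SNV
sites x samples, diploid genotypes coded as alternate-allele counts
(0, 1, 2) with ``MISSING = -1``.  Positions are 1-based internally (the VCF
convention); every window/region written out uses BED-style 0-based
half-open coordinates.  The conversion happens exactly once, at the output
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MISSING = -1

#: INFO keys and the hard-filter rule attached to each: (operator, threshold).
#: A site is removed when ANY criterion fires; a missing key cannot fire.
HARD_FILTERS = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}

_NUCS = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Malformed VCF content (names the failing record where known)."""


class SampleLookupError(KeyError):
    """A requested sample is absent from the VCF or population map."""


@dataclass
class VariantTable:
    """Biallelic SNV genotype matrix with per-site metadata.

    Attributes
    ----------
    chrom, pos : arrays of length n_sites; ``pos`` is 1-based (VCF).
    ref, alt : single-nucleotide allele symbols per site.
    genotypes : ``(n_sites, n_samples)`` int8 array of alternate-allele
        counts in {0, 1, 2} with ``MISSING`` (= -1) for uncalled genotypes.
    samples : sample identifiers, column order of ``genotypes``.
    info : optional per-site DataFrame of numeric annotations (QD, FS, ...);
        NaN marks an absent key.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = list(self.samples)
        if self.genotypes.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take(self, idx) -> "VariantTable":
        """Row-subset (sites) by integer or boolean index, order preserved."""
        idx = np.asarray(idx)
        info = None if self.info is None else self.info.iloc[np.flatnonzero(idx) if idx.dtype == bool else idx].reset_index(drop=True)
        return VariantTable(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx],
            self.genotypes[idx], self.samples, info,
        )

    def subset_samples(self, samples) -> "VariantTable":
        """Column-subset to the given samples, in the given order."""
        lookup = {s: j for j, s in enumerate(self.samples)}
        try:
            cols = [lookup[s] for s in samples]
        except KeyError as e:
            raise SampleLookupError(f"sample {e.args[0]!r} not in table") from None
        return replace(self, genotypes=self.genotypes[:, cols], samples=list(samples))

    def sample_indices(self, samples) -> np.ndarray:
        lookup = {s: j for j, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.intp)
        except KeyError as e:
            raise SampleLookupError(f"sample {e.args[0]!r} not in table") from None


@dataclass
class PopulationMap:
    """sample id -> population label, with convenience accessors."""

    assignments: dict[str, str]

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def samples_for(self, pop: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == pop]
        if not out:
            raise SampleLookupError(f"population {pop!r} has no samples")
        return out

    def __len__(self) -> int:
        return len(self.assignments)


def _is_biallelic_snv(ref: str, alts) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in _NUCS
        and alts[0].upper() in _NUCS
    )


def read_vcf(path, samples=None, info_keys=tuple(HARD_FILTERS)) -> VariantTable:
    """Read a VCF, keeping only biallelic SNV records.

    Multiallelic and non-SNV records in the input are silently skipped.
    ``./.`` and half-called genotypes map to ``MISSING``; phased and unphased
    separators are treated identically.  Duplicate (chrom, pos) records keep
    the first occurrence.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as e:  # htslib raises assorted OSError/ValueError
        raise VcfFormatError(f"cannot parse VCF {path}: {e}") from e
    all_samples = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in all_samples]
        if missing:
            raise SampleLookupError(f"samples not in VCF: {missing}")
        vcf.close()
        vcf = VCF(str(path), samples=list(samples))
    names = list(vcf.samples)

    chrom, pos, ref, alt, rows, info_rows = [], [], [], [], [], []
    seen: set[tuple[str, int]] = set()
    record_no = 0
    it = iter(vcf)
    while True:
        try:
            v = next(it)
        except StopIteration:
            break
        except Exception as e:
            raise VcfFormatError(f"malformed VCF record {record_no + 1}: {e}") from e
        record_no += 1
        if not _is_biallelic_snv(v.REF, v.ALT):
            continue
        key = (v.CHROM, v.POS)
        if key in seen:
            continue
        seen.add(key)
        try:
            gts = v.genotypes
            row = np.empty(len(names), dtype=np.int8)
            for j, g in enumerate(gts):
                a, b = g[0], g[1]
                row[j] = MISSING if (a < 0 or b < 0) else (a > 0) + (b > 0)
        except Exception as e:
            raise VcfFormatError(f"malformed genotype field in record {record_no}: {e}") from e
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(row)
        info_rows.append([_info_float(v, k) for k in info_keys])
    vcf.close()

    g = np.vstack(rows) if rows else np.empty((0, len(names)), dtype=np.int8)
    info = pd.DataFrame(info_rows, columns=list(info_keys), dtype=float) if info_keys else None
    vt = VariantTable(chrom, pos, ref, alt, g, names, info)
    if samples is not None and list(samples) != names:
        vt = vt.subset_samples(list(samples))  # htslib keeps file order
    order = np.lexsort((vt.pos, vt.chrom.astype(str)))
    if not np.array_equal(order, np.arange(vt.n_sites)):
        vt = vt.take(order)
    return vt


def _info_float(v, key):
    x = v.INFO.get(key)
    if x is None:
        return np.nan
    try:
        return float(x)
    except (TypeError, ValueError):
        return np.nan


def write_vcf(vt: VariantTable, path, contigs=None) -> None:
    """Write a VariantTable as a minimal VCF v4.2 text file."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for c, ln in contigs.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(vt.samples) + "\n")
        for i in range(vt.n_sites):
            gts = "\t".join(code[int(g)] for g in vt.genotypes[i])
            fh.write(
                f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{vt.alt[i]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def hard_filter_sites(vt: VariantTable) -> VariantTable:
    """Remove sites failing any hard-filter criterion (QD/FS/MQ/RankSums).

    A site is dropped when QD < 2.0, FS > 60.0, MQ < 40.0,
    MQRankSum < -12.5 or ReadPosRankSum < -8.0.  A missing INFO key cannot
    fire its criterion (NaN comparisons are False), so annotation-free
    tables pass through unchanged.  Idempotent; order preserved.
    """
    if vt.info is None or vt.n_sites == 0:
        return vt
    fail = np.zeros(vt.n_sites, dtype=bool)
    for key, (op, thr) in HARD_FILTERS.items():
        if key not in vt.info.columns:
            continue
        x = vt.info[key].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            fail |= (x < thr) if op == "<" else (x > thr)
    return vt.take(~fail)


def drop_missing_sites(vt: VariantTable) -> VariantTable:
    """Keep only sites called in every sample (no MISSING codes)."""
    keep = ~(vt.genotypes == MISSING).any(axis=1)
    return vt.take(keep)


def read_population_map(path) -> PopulationMap:
    """Two-column text (sample, population); '#' comments and blanks allowed."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise VcfFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            sample, pop = parts
            if sample in assignments:
                raise VcfFormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
    return PopulationMap(assignments)


def write_population_map(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("# sample\tpopulation\n")
        for s, p in pm.assignments.items():
            fh.write(f"{s}\t{p}\n")


def read_contig_index(path) -> dict[str, int]:
    ci: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            ci[name] = int(length)
    if any(v <= 0 for v in ci.values()):
        raise ValueError("contig lengths must be positive")
    return ci


def write_contig_index(ci: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for c, ln in ci.items():
            fh.write(f"{c}\t{ln}\n")


def write_stats_table(df: pd.DataFrame, path) -> None:
    """Tab-separated output with header; floats at 12 significant digits.

    Window coordinates in ``df`` are expected to already be BED-style
    0-based half-open (the pipeline keeps them that way in every table).
    """
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_stats_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: pd.DataFrame, path, extra_cols=()) -> None:
    """Write (chrom, start, end[, extra...]) as BED (0-based half-open)."""
    cols = ["chrom", "start", "end", *extra_cols]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def check_contigs(vt: VariantTable, ci: dict[str, int]) -> None:
    """Every VariantTable contig must be present in the index, in range."""
    for c in pd.unique(vt.chrom):
        if c not in ci:
            raise ValueError(f"contig {c!r} missing from contig index")
        m = vt.pos[vt.chrom == c]
        if m.size and m.max() > ci[c]:
            raise ValueError(f"position beyond contig {c!r} length {ci[c]}")
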