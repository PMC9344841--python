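"""Reference-panel and read-count I/O.

The estimator consumes two inputs: a haplotype reference panel for the X
chromosome and per-marker read counts derived from a samtools-style pileup.
This module defines the in-memory containers (:class:`ReferencePanel`,
:class:`ReadCountTable`), readers/writers for the panel in both an HDF5
container and a human-readable tab-separated dialect, a builder that derives
a panel from a phased VCF plus a genetic map, and the pileup parser.

Coordinates are 1-based inclusive throughout, matching pileup and VCF
conventions.  Downstream code never sees physical positions: a
:class:`ReadCountTable` stores indices into the panel's marker list.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class PanelFormatError(ValueError):
    """Raised when a panel file violates the format or an invariant."""


class PileupParseError(ValueError):
    """Raised when a pileup line cannot be decoded."""


@dataclass
class ReferencePanel:
    """A haplotype reference panel over L biallelic X-chromosome markers.

    Parameters
    ----------
    haplotypes
        Binary matrix of shape (n, L); entry ``[i, l]`` is 0 if haplotype
        ``i`` carries the reference allele at marker ``l`` and 1 for the
        alternative allele.  No missingness is allowed.
    chrom
        Chromosome label, normally ``"X"``; stored as given.
    positions
        1-based physical positions, strictly increasing, length L.
    ref_allele, alt_allele
        Single-base allele labels from {A, C, G, T}, length L each.
    genetic_map
        Cumulative genetic positions in Morgans, non-decreasing, length L.
    pop_freqs
        Mapping from population label to a length-L vector of
        alternative-allele frequencies in [0, 1].  One of these columns is
        later selected as the contaminant allele-frequency proxy.
    """

    haplotypes: np.ndarray
    chrom: str
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    genetic_map: np.ndarray
    pop_freqs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype="U1")
        self.alt_allele = np.asarray(self.alt_allele, dtype="U1")
        self.genetic_map = np.asarray(self.genetic_map, dtype=np.float64)
        self.pop_freqs = {
            k: np.asarray(v, dtype=np.float64) for k, v in self.pop_freqs.items()
        }
        self.validate()

    def validate(self) -> None:
        n, L = self.haplotypes.shape
        if n < 1 or L < 1:
            raise PanelFormatError("panel must have at least 1 haplotype and 1 marker")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise PanelFormatError("haplotype entries must all be 0 or 1")
        for name, arr in (
            ("positions", self.positions),
            ("ref_allele", self.ref_allele),
            ("alt_allele", self.alt_allele),
            ("genetic_map", self.genetic_map),
        ):
            if len(arr) != L:
                raise PanelFormatError(f"{name} has length {len(arr)}, expected {L}")
        if L > 1 and not (np.diff(self.positions) > 0).all():
            bad = int(np.flatnonzero(np.diff(self.positions) <= 0)[0]) + 1
            raise PanelFormatError(
                f"positions not strictly increasing at marker {bad} "
                f"(position {self.positions[bad]})"
            )
        if L > 1 and not (np.diff(self.genetic_map) >= 0).all():
            bad = int(np.flatnonzero(np.diff(self.genetic_map) < 0)[0]) + 1
            raise PanelFormatError(f"genetic map decreases at marker {bad}")
        for allele in np.concatenate([self.ref_allele, self.alt_allele]):
            if allele not in _VALID_BASES:
                raise PanelFormatError(f"allele label {allele!r} outside A/C/G/T")
        if (self.ref_allele == self.alt_allele).any():
            bad = int(np.flatnonzero(self.ref_allele == self.alt_allele)[0])
            raise PanelFormatError(f"ref == alt at marker {bad}")
        for pop, freqs in self.pop_freqs.items():
            if len(freqs) != L:
                raise PanelFormatError(f"pop_freqs[{pop!r}] has wrong length")
            if ((freqs < 0) | (freqs > 1)).any():
                bad = int(np.flatnonzero((freqs < 0) | (freqs > 1))[0])
                raise PanelFormatError(
                    f"pop_freqs[{pop!r}] outside [0,1] at marker {bad}"
                )

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Panel-wide empirical alternative-allele frequency per marker."""
        return self.haplotypes.mean(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferencePanel):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.haplotypes, other.haplotypes)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref_allele, other.ref_allele)
            and np.array_equal(self.alt_allele, other.alt_allele)
            and np.array_equal(self.genetic_map, other.genetic_map)
            and list(self.pop_freqs) == list(other.pop_freqs)
            and all(
                np.array_equal(self.pop_freqs[k], other.pop_freqs[k])
                for k in self.pop_freqs
            )
        )


@dataclass
class ReadCountTable:
    """Per-marker reference/alternative read counts.

    Only markers with at least one aligned sequence are listed;
    ``marker_index`` holds sorted, unique indices into the panel's markers.
    """

    marker_index: np.ndarray
    n_ref: np.ndarray
    n_alt: np.ndarray

    def __post_init__(self) -> None:
        self.marker_index = np.asarray(self.marker_index, dtype=np.int64)
        self.n_ref = np.asarray(self.n_ref, dtype=np.int64)
        self.n_alt = np.asarray(self.n_alt, dtype=np.int64)
        if not (len(self.marker_index) == len(self.n_ref) == len(self.n_alt)):
            raise ValueError("marker_index, n_ref, n_alt must have equal length")
        if len(self.marker_index) > 1 and not (np.diff(self.marker_index) > 0).all():
            raise ValueError("marker_index must be sorted and unique")
        if (self.n_ref < 0).any() or (self.n_alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if ((self.n_ref + self.n_alt) < 1).any():
            raise ValueError("every listed marker must have depth >= 1")

    @property
    def n_sites(self) -> int:
        return len(self.marker_index)

    @property
    def depth(self) -> np.ndarray:
        return self.n_ref + self.n_alt

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadCountTable):
            return NotImplemented
        return (
            np.array_equal(self.marker_index, other.marker_index)
            and np.array_equal(self.n_ref, other.n_ref)
            and np.array_equal(self.n_alt, other.n_alt)
        )


# ---------------------------------------------------------------------------
# Panel container I/O
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    """Format a float so it round-trips exactly through the text dialect."""
    return format(float(x), ".17g")


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    """Write a panel; HDF5 for ``.h5``/``.hdf5`` paths, text dialect otherwise.

    The text dialect has optional ``#key=value`` metadata lines, then a
    header naming the columns, then one tab-separated row per marker with
    the n haplotype alleles packed into a contiguous 0/1 string.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_panel_h5(panel, path)
    else:
        _write_panel_text(panel, path)


def load_panel(path: str | Path) -> ReferencePanel:
    """Load a panel written by :func:`write_panel` (either dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if h5py.is_hdf5(path):
        return _load_panel_h5(path)
    return _load_panel_text(path)


def _write_panel_h5(panel: ReferencePanel, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["chrom"] = panel.chrom
        f.create_dataset("haplotypes", data=panel.haplotypes, dtype=np.uint8)
        f.create_dataset("positions", data=panel.positions)
        f.create_dataset("ref_allele", data=panel.ref_allele.astype("S1"))
        f.create_dataset("alt_allele", data=panel.alt_allele.astype("S1"))
        f.create_dataset("genetic_map", data=panel.genetic_map)
        grp = f.create_group("pop_freqs")
        grp.attrs["order"] = list(panel.pop_freqs)
        for pop, freqs in panel.pop_freqs.items():
            grp.create_dataset(pop, data=freqs)


def _load_panel_h5(path: Path) -> ReferencePanel:
    with h5py.File(path, "r") as f:
        order = list(f["pop_freqs"].attrs.get("order", sorted(f["pop_freqs"])))
        return ReferencePanel(
            haplotypes=f["haplotypes"][()],
            chrom=str(f.attrs["chrom"]),
            positions=f["positions"][()],
            ref_allele=f["ref_allele"][()].astype("U1"),
            alt_allele=f["alt_allele"][()].astype("U1"),
            genetic_map=f["genetic_map"][()],
            pop_freqs={pop: f["pop_freqs"][pop][()] for pop in order},
        )


def _write_panel_text(panel: ReferencePanel, path: Path) -> None:
    pops = list(panel.pop_freqs)
    with open(path, "w") as f:
        f.write(f"#chrom={panel.chrom}\n")
        header = ["pos", "ref", "alt", "map", "haplotypes"] + [f"af_{p}" for p in pops]
        f.write("\t".join(header) + "\n")
        for l in range(panel.n_markers):
            row = [
                str(int(panel.positions[l])),
                panel.ref_allele[l],
                panel.alt_allele[l],
                _fmt(panel.genetic_map[l]),
                "".join(str(int(a)) for a in panel.haplotypes[:, l]),
            ]
            row += [_fmt(panel.pop_freqs[p][l]) for p in pops]
            f.write("\t".join(row) + "\n")


def _load_panel_text(path: Path) -> ReferencePanel:
    chrom = "X"
    header: list[str] | None = None
    positions: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    gmap: list[float] = []
    hap_strings: list[str] = []
    pop_cols: dict[str, list[float]] = {}
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#(\w+)=(.*)$", line)
                if m and m.group(1) == "chrom":
                    chrom = m.group(2)
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["pos", "ref", "alt", "map", "haplotypes"]
                if header[: len(expected)] != expected:
                    raise PanelFormatError(
                        f"{path}: line {lineno}: malformed header {header!r}"
                    )
                for col in header[len(expected):]:
                    if not col.startswith("af_"):
                        raise PanelFormatError(
                            f"{path}: line {lineno}: unexpected column {col!r}"
                        )
                    pop_cols[col[3:]] = []
                continue
            if len(fields) != len(header):
                raise PanelFormatError(
                    f"{path}: line {lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            try:
                positions.append(int(fields[0]))
                ref.append(fields[1])
                alt.append(fields[2])
                gmap.append(float(fields[3]))
                hap_strings.append(fields[4])
                for pop, value in zip(pop_cols, fields[5:]):
                    pop_cols[pop].append(float(value))
            except ValueError as exc:
                raise PanelFormatError(f"{path}: line {lineno}: {exc}") from exc
    if header is None or not positions:
        raise PanelFormatError(f"{path}: no marker records found")
    n = len(hap_strings[0])
    if any(len(s) != n or set(s) - {"0", "1"} for s in hap_strings):
        raise PanelFormatError(f"{path}: inconsistent or non-binary haplotype column")
    haps = np.array(
        [[int(ch) for ch in s] for s in hap_strings], dtype=np.uint8
    ).T  # markers x haps -> haps x markers
    try:
        return ReferencePanel(
            haplotypes=haps,
            chrom=chrom,
            positions=np.array(positions),
            ref_allele=np.array(ref),
            alt_allele=np.array(alt),
            genetic_map=np.array(gmap),
            pop_freqs={p: np.array(v) for p, v in pop_cols.items()},
        )
    except PanelFormatError as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Panel construction from VCF + genetic map
# ---------------------------------------------------------------------------

def load_genetic_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a tab-separated genetic map: columns position_bp, map_Morgan."""
    pos, morgan = [], []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: need two columns")
            pos.append(int(fields[0]))
            morgan.append(float(fields[1]))
    pos_a, morgan_a = np.array(pos, dtype=np.int64), np.array(morgan)
    order = np.argsort(pos_a)
    return pos_a[order], morgan_a[order]


def build_panel_from_vcf(
    vcf_path: str | Path,
    map_path: str | Path,
    maf_min: float = 0.05,
    populations: Mapping[str, Sequence[str]] | None = None,
) -> ReferencePanel:
    """Build a reference panel from a phased VCF and a genetic map.

    Keeps biallelic SNVs with panel-wide minor allele frequency strictly
    greater than ``maf_min``.  Each phase of a diploid phased genotype is
    counted as one haplotype; haploid genotypes (male X) contribute one.
    Genetic positions are linearly interpolated from the map and clamped to
    its endpoints outside its range (with a warning).

    ``populations`` maps a population label to the sample names belonging to
    it; the alternative-allele frequency of each listed population becomes a
    ``pop_freqs`` column.  A panel-wide ``"ALL"`` column is always included.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    populations = dict(populations or {})
    for pop, members in populations.items():
        missing = set(members) - set(samples)
        if missing:
            raise ValueError(f"population {pop!r}: samples {sorted(missing)} not in VCF")

    chrom = None
    positions, ref, alt = [], [], []
    hap_cols: list[np.ndarray] = []        # one (n_hap,) allele vector per marker
    hap_sample: list[str] = []             # sample name of each haplotype, fixed order
    n_skipped_multiallelic = 0
    n_skipped_maf = 0

    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped_multiallelic += 1
            continue
        if var.REF not in _VALID_BASES or var.ALT[0] not in _VALID_BASES:
            n_skipped_multiallelic += 1
            continue
        alleles: list[int] = []
        owners: list[str] = []
        for sample, gt in zip(samples, var.genotypes):
            calls = [a for a in gt[:-1] if a >= 0]  # last element is phase flag
            for a in calls:
                alleles.append(a)
                owners.append(sample)
        if not alleles:
            continue
        if not hap_sample:
            hap_sample = owners
        col = np.array(alleles, dtype=np.uint8)
        af = col.mean()
        maf = min(af, 1.0 - af)
        if maf <= maf_min:
            n_skipped_maf += 1
            continue
        if chrom is None:
            chrom = var.CHROM
        positions.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        hap_cols.append(col)

    if n_skipped_multiallelic:
        logger.info("skipped %d non-biallelic-SNV records", n_skipped_multiallelic)
    if n_skipped_maf:
        logger.info("skipped %d records with MAF <= %g", n_skipped_maf, maf_min)
    if not positions:
        raise ValueError(f"{vcf_path}: no markers passed the filters")

    haps = np.stack(hap_cols, axis=1)  # n_hap x L
    pos_arr = np.array(positions, dtype=np.int64)
    map_pos, map_morgan = load_genetic_map(map_path)
    if pos_arr.min() < map_pos.min() or pos_arr.max() > map_pos.max():
        logger.warning(
            "markers outside genetic-map range [%d, %d]; clamped to endpoints",
            map_pos.min(), map_pos.max(),
        )
    gmap = np.interp(pos_arr, map_pos, map_morgan)

    owner_arr = np.array(hap_sample)
    pop_freqs: dict[str, np.ndarray] = {"ALL": haps.mean(axis=0)}
    for pop, members in populations.items():
        mask = np.isin(owner_arr, list(members))
        if not mask.any():
            raise ValueError(f"population {pop!r} contributed no haplotypes")
        pop_freqs[pop] = haps[mask].mean(axis=0)

    return ReferencePanel(
        haplotypes=haps,
        chrom=chrom or "X",
        positions=pos_arr,
        ref_allele=np.array(ref),
        alt_allele=np.array(alt),
        genetic_map=gmap,
        pop_freqs=pop_freqs,
    )


# ---------------------------------------------------------------------------
# Pileup parsing
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"[+-](\d+)")


def decode_pileup_bases(bases: str, quals: str, ref: str) -> list[tuple[str, int]]:
    """Decode a pileup base column into (base, phred_quality) pairs.

    Strips read start (``^`` + mapping quality char) and end (``$``) marks
    and indel spans (``+N.../−N...``); deletion placeholders (``*``/``#``)
    and reference skips (``>``/``<``) consume a quality character but yield
    no base.  ``.``/``,`` become the reference base; letters are upper-cased.
    """
    out: list[tuple[str, int]] = []
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # caret plus mapping-quality char
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise PileupParseError(f"malformed indel at offset {i} in {bases!r}")
            span = int(m.group(1))
            i = m.end() + span
            continue
        if qi >= len(quals):
            raise PileupParseError(
                f"base column {bases!r} longer than quality column {quals!r}"
            )
        q = ord(quals[qi]) - 33
        qi += 1
        if ch in ".,":
            out.append((ref.upper(), q))
        elif ch.upper() in "ACGTN":
            out.append((ch.upper(), q))
        elif ch in "*#><":
            pass  # deletion placeholder / reference skip: no base call
        else:
            raise PileupParseError(f"unexpected pileup character {ch!r} in {bases!r}")
        i += 1
    if qi != len(quals):
        raise PileupParseError(
            f"quality column {quals!r} longer than decoded bases in {bases!r}"
        )
    return out


def parse_pileup(
    path: str | Path,
    panel: ReferencePanel,
    min_bq: int = 20,
) -> ReadCountTable:
    """Convert samtools-pileup text into a :class:`ReadCountTable`.

    For every panel marker present in the pileup, bases with quality >=
    ``min_bq`` matching ``ref_allele`` are counted into ``n_ref`` and those
    matching ``alt_allele`` into ``n_alt``.  Bases matching neither allele
    are discarded (the emission model is strictly biallelic) and tallied in
    a logged counter, as are lines whose chromosome does not match the
    panel.  Positions absent from the panel are ignored.  Mapping-quality
    filtering is assumed to have been applied when the pileup was generated.
    """
    pos_to_idx = {int(p): l for l, p in enumerate(panel.positions)}
    n_ref = np.zeros(panel.n_markers, dtype=np.int64)
    n_alt = np.zeros(panel.n_markers, dtype=np.int64)
    n_other = 0
    n_chrom_mismatch = 0
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                fields = line.split()
            if len(fields) < 6:
                raise PileupParseError(
                    f"{path}: line {lineno}: expected 6 pileup columns"
                )
            chrom, pos_s, ref, _depth, bases, quals = fields[:6]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise PileupParseError(
                    f"{path}: line {lineno}: bad position {pos_s!r}"
                ) from exc
            if chrom != panel.chrom:
                n_chrom_mismatch += 1
                continue
            idx = pos_to_idx.get(pos)
            if idx is None:
                continue
            try:
                calls = decode_pileup_bases(bases, quals, ref)
            except PileupParseError as exc:
                raise PileupParseError(f"{path}: line {lineno}: {exc}") from exc
            for base, q in calls:
                if q < min_bq:
                    continue
                if base == panel.ref_allele[idx]:
                    n_ref[idx] += 1
                elif base == panel.alt_allele[idx]:
                    n_alt[idx] += 1
                else:
                    n_other += 1
    if n_other:
        logger.info("discarded %d bases matching neither ref nor alt", n_other)
    if n_chrom_mismatch:
        logger.info("ignored %d pileup lines on other chromosomes", n_chrom_mismatch)
    covered = np.flatnonzero(n_ref + n_alt >= 1)
    return ReadCountTable(
        marker_index=covered, n_ref=n_ref[covered], n_alt=n_alt[covered]
    )


def pileup_base_tallies(
    path: str | Path,
    chrom: str,
    min_bq: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tally per-position matches/mismatches against the pileup's own
    reference column.

    Returns (positions, n_match, n_mismatch) over all pileup lines on
    ``chrom``, counting only bases with quality >= ``min_bq``.  Used to
    estimate the per-base error rate from monomorphic flanking sites.
    """
    positions: list[int] = []
    match: list[int] = []
    mismatch: list[int] = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                fields = line.split()
            if len(fields) < 6:
                raise PileupParseError(
                    f"{path}: line {lineno}: expected 6 pileup columns"
                )
            c, pos_s, ref, _d, bases, quals = fields[:6]
            if c != chrom:
                continue
            calls = decode_pileup_bases(bases, quals, ref)
            n_m = sum(1 for b, q in calls if q >= min_bq and b == ref.upper())
            n_x = sum(
                1 for b, q in calls if q >= min_bq and b != ref.upper() and b != "N"
            )
            if n_m + n_x:
                positions.append(int(pos_s))
                match.append(n_m)
                mismatch.append(n_x)
    return (
        np.array(positions, dtype=np.int64),
        np.array(match, dtype=np.int64),
        np.array(mismatch, dtype=np.int64),
    )
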