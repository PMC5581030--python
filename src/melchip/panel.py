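"""Mutation panel definition, HGVS-c parsing, label validation, and chip layout.

The assay interrogates 39 recurrent melanoma driver mutations in BRAF, NRAS,
KIT, GNAQ, GNA11, MAP2K1 and MAP2K2.  Probes are organised in *locus groups*:
all probes of a group interrogate one amplified locus and share a single
wild-type probe.  Every probe (mutant and wild-type) is spotted in duplicate,
and four Cy5 marker spots sit at the corners of the grid so that the spot grid
can be located on an acquired image.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from Bio.Seq import Seq

PANEL_GENES = ("BRAF", "NRAS", "KIT", "GNAQ", "GNA11", "MAP2K1", "MAP2K2")

#: genes whose driver mutations are treated as mutually exclusive;
#: MAP2K1/2 variants may accompany BRAF mutations and are deliberately absent.
EXCLUSIVE_GENES = frozenset({"BRAF", "NRAS", "KIT", "GNAQ", "GNA11"})


class HgvsParseError(ValueError):
    """Raised when an HGVS c. string cannot be parsed."""


class PanelError(ValueError):
    """Raised for malformed panels or layouts."""


# ---------------------------------------------------------------------------
# HGVS c. parsing
# ---------------------------------------------------------------------------

_RE_SUB = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_RE_DELINS = re.compile(r"^c\.(\d+)_(\d+)del([ACGT]+)ins([ACGT]+)$")
_RE_DELINS_SHORT = re.compile(r"^c\.(\d+)_(\d+)([ACGT]+)>([ACGT]+)$")
_RE_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


@dataclass(frozen=True)
class HgvsChange:
    """A parsed coding-DNA change.

    ``start``/``end`` are 1-based CDS positions.  For substitutions
    ``start == end``; for insertions the change falls *between* ``start``
    and ``end`` (which must be adjacent) and ``ref`` is empty.
    """

    kind: str  # "substitution" | "delins" | "insertion"
    start: int
    end: int
    ref: str
    alt: str

    def canonical(self) -> str:
        if self.kind == "substitution":
            return f"c.{self.start}{self.ref}>{self.alt}"
        if self.kind == "delins":
            return f"c.{self.start}_{self.end}del{self.ref}ins{self.alt}"
        return f"c.{self.start}_{self.end}ins{self.alt}"


def parse_hgvs_c(text: str) -> HgvsChange:
    """Parse an HGVS coding-DNA description into a structured change.

    Supports single-base substitutions (``c.1799T>A``), multi-base
    deletion-insertions in both ``del..ins..`` and ``NN>NN`` spellings
    (``c.1798_1799delGTinsAA``, ``c.1799_1800TG>AC``) and insertions
    (``c.1797_1798insACA``).
    """
    if not isinstance(text, str) or not text.startswith("c."):
        raise HgvsParseError(f"not an HGVS c. description: {text!r}")
    m = _RE_SUB.match(text)
    if m:
        pos = int(m.group(1))
        return HgvsChange("substitution", pos, pos, m.group(2), m.group(3))
    m = _RE_DELINS.match(text)
    if m is None:
        m = _RE_DELINS_SHORT.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        ref, alt = m.group(3), m.group(4)
        if end < start:
            raise HgvsParseError(f"inverted range {start}_{end} in {text!r}")
        if len(ref) != end - start + 1:
            raise HgvsParseError(
                f"deleted bases {ref!r} do not span {start}_{end} in {text!r}"
            )
        return HgvsChange("delins", start, end, ref, alt)
    m = _RE_INS.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise HgvsParseError(
                f"insertion flanks {start}_{end} are not adjacent in {text!r}"
            )
        return HgvsChange("insertion", start, end, "", m.group(3))
    # name the offending token: first thing after "c." that breaks the grammar
    raise HgvsParseError(f"malformed HGVS c. description: {text!r}")


# ---------------------------------------------------------------------------
# Panel entries and the packaged 39-mutation catalogue
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    protein_change: str
    cdna_change: str
    group_id: str

    def __post_init__(self) -> None:
        if self.gene not in PANEL_GENES:
            raise PanelError(f"{self.gene} is not a panel gene")
        parse_hgvs_c(self.cdna_change)  # raises on malformed syntax

    @property
    def probe_id(self) -> str:
        return f"{self.gene}:{self.cdna_change}"

    @property
    def change(self) -> HgvsChange:
        return parse_hgvs_c(self.cdna_change)

    @property
    def codon_number(self) -> int:
        m = re.match(r"^[A-Z](\d+)", self.protein_change)
        if m is None:
            raise PanelError(f"cannot read codon from {self.protein_change!r}")
        return int(m.group(1))


@dataclass(frozen=True)
class LocusGroup:
    group_id: str
    entries: tuple[PanelEntry, ...]

    @property
    def wt_probe_id(self) -> str:
        return f"WT:{self.group_id}"


@dataclass(frozen=True)
class MutationPanel:
    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.gene, e.cdna_change)
            if key in seen:
                raise PanelError(f"duplicate panel entry {key}")
            seen.add(key)

    @property
    def groups(self) -> tuple[LocusGroup, ...]:
        order: dict[str, list[PanelEntry]] = {}
        for e in self.entries:
            order.setdefault(e.group_id, []).append(e)
        return tuple(LocusGroup(g, tuple(v)) for g, v in order.items())

    def group(self, group_id: str) -> LocusGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def by_probe_id(self, probe_id: str) -> PanelEntry:
        for e in self.entries:
            if e.probe_id == probe_id:
                return e
        raise KeyError(probe_id)

    def gene_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.gene] = counts.get(e.gene, 0) + 1
        return counts


def load_default_panel() -> MutationPanel:
    """The packaged 39-entry catalogue of targeted melanoma mutations."""
    text = resources.files("melchip.data").joinpath("panel.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    entries = []
    for ln in lines[1:]:
        rec = dict(zip(header, ln.split("\t")))
        entries.append(
            PanelEntry(rec["gene"], rec["protein_change"], rec["cdna_change"], rec["group_id"])
        )
    return MutationPanel(tuple(entries))


# ---------------------------------------------------------------------------
# Codon contexts and protein-label validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonContext:
    """A short coding-strand CDS window with known coordinates around one codon."""

    gene: str
    codon_number: int
    cds_start: int  # 1-based CDS coordinate of sequence[0]
    sequence: str

    def __post_init__(self) -> None:
        # the window must contain the whole target codon, in frame
        first, last = self.codon_span()
        if first < self.cds_start or last > self.cds_start + len(self.sequence) - 1:
            raise PanelError("context window does not cover its codon")

    def codon_span(self) -> tuple[int, int]:
        return 3 * self.codon_number - 2, 3 * self.codon_number

    def ref_codon(self) -> str:
        first, _ = self.codon_span()
        i = first - self.cds_start
        return self.sequence[i : i + 3]

    def covers(self, change: HgvsChange) -> bool:
        lo = self.cds_start
        hi = self.cds_start + len(self.sequence) - 1
        return lo <= change.start and change.end <= hi

    def apply(self, change: HgvsChange) -> str:
        """Return the window sequence with *change* applied (same coordinates)."""
        if not self.covers(change):
            raise PanelError(
                f"{change.canonical()} outside context "
                f"{self.gene} codon {self.codon_number}"
            )
        i = change.start - self.cds_start
        j = change.end - self.cds_start + 1
        if change.kind == "substitution" or change.kind == "delins":
            if self.sequence[i:j] != change.ref:
                raise PanelError(
                    f"reference mismatch: context has {self.sequence[i:j]!r}, "
                    f"change expects {change.ref!r}"
                )
            return self.sequence[:i] + change.alt + self.sequence[j:]
        # insertion between start and end
        return self.sequence[: i + 1] + change.alt + self.sequence[i + 1 :]


def load_codon_contexts() -> dict[tuple[str, int], CodonContext]:
    raw = json.loads(
        resources.files("melchip.data").joinpath("codon_contexts.json").read_text()
    )
    out = {}
    for rec in raw["contexts"]:
        ctx = CodonContext(rec["gene"], rec["codon_number"], rec["cds_start"], rec["sequence"])
        out[(ctx.gene, ctx.codon_number)] = ctx
    return out


_RE_PROTEIN = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class ValidationVerdict:
    consistent: bool
    expected_aa: str
    observed_aa: str
    mutant_codon: str
    message: str = ""


def validate_entry(entry: PanelEntry, ctx: CodonContext) -> ValidationVerdict:
    """Check a panel entry's protein label against its cDNA change.

    Applies the change to the context window, translates the target codon with
    the standard genetic code, and compares reference and alternate amino
    acids with the single-letter label (e.g. ``V600E``).
    """
    m = _RE_PROTEIN.match(entry.protein_change)
    if m is None:
        raise PanelError(f"unsupported protein label {entry.protein_change!r}")
    ref_aa, codon_number, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    if codon_number != ctx.codon_number or entry.gene != ctx.gene:
        raise PanelError("context does not match entry locus")

    observed_ref = str(Seq(ctx.ref_codon()).translate())
    if observed_ref != ref_aa:
        return ValidationVerdict(
            False, ref_aa, observed_ref, ctx.ref_codon(),
            f"reference codon translates to {observed_ref}, label says {ref_aa}",
        )
    change = entry.change
    mutated = ctx.apply(change)
    first, _ = ctx.codon_span()
    i = first - ctx.cds_start
    mutant_codon = mutated[i : i + 3]
    observed_alt = str(Seq(mutant_codon).translate())
    if observed_alt != alt_aa:
        return ValidationVerdict(
            False, alt_aa, observed_alt, mutant_codon,
            f"mutant codon {mutant_codon} translates to {observed_alt}, "
            f"label says {alt_aa}",
        )
    return ValidationVerdict(True, alt_aa, observed_alt, mutant_codon)


def validate_panel(panel: MutationPanel,
                   contexts: Mapping[tuple[str, int], CodonContext] | None = None
                   ) -> list[tuple[PanelEntry, ValidationVerdict]]:
    """Validate every panel entry; returns (entry, verdict) pairs."""
    if contexts is None:
        contexts = load_codon_contexts()
    out = []
    for e in panel.entries:
        ctx = contexts[(e.gene, e.codon_number)]
        out.append((e, validate_entry(e, ctx)))
    return out


# ---------------------------------------------------------------------------
# Chip layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpotRole:
    kind: str  # "mutant" | "wt" | "marker" | "empty"
    probe_id: str | None = None
    group_id: str | None = None


@dataclass(frozen=True)
class LayoutGeometry:
    rows: int = 10
    cols: int = 12
    pitch: float = 20.0   # centre-to-centre spacing, px
    radius: float = 6.0   # nominal spot radius, px
    margin: float = 16.0  # image border to first spot centre, px


@dataclass(frozen=True)
class ChipLayout:
    geometry: LayoutGeometry
    spot_map: Mapping[int, SpotRole] = field(hash=False)

    @property
    def rows(self) -> int:
        return self.geometry.rows

    @property
    def cols(self) -> int:
        return self.geometry.cols

    @property
    def marker_spots(self) -> tuple[int, ...]:
        return tuple(sorted(i for i, r in self.spot_map.items() if r.kind == "marker"))

    @property
    def occupied(self) -> tuple[int, ...]:
        return tuple(sorted(i for i, r in self.spot_map.items() if r.kind != "empty"))

    def duplicate_pairs(self) -> dict[str, tuple[int, int]]:
        pairs: dict[str, list[int]] = {}
        for i, role in sorted(self.spot_map.items()):
            if role.probe_id is not None:
                pairs.setdefault(role.probe_id, []).append(i)
        out = {}
        for pid, idxs in pairs.items():
            if len(idxs) != 2:
                raise PanelError(f"probe {pid} occupies {len(idxs)} spots, expected 2")
            out[pid] = (idxs[0], idxs[1])
        return out

    def grid_position(self, index: int) -> tuple[int, int]:
        return divmod(index, self.cols)

    def group_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for i, role in sorted(self.spot_map.items()):
            if role.group_id is not None and role.group_id not in seen:
                seen.append(role.group_id)
        return tuple(seen)

    # -- manifest (JSON) round-trip -------------------------------------

    def to_manifest(self) -> dict:
        g = self.geometry
        return {
            "geometry": {"rows": g.rows, "cols": g.cols, "pitch": g.pitch,
                         "radius": g.radius, "margin": g.margin},
            "spots": {
                str(i): {"kind": r.kind, "probe_id": r.probe_id, "group_id": r.group_id}
                for i, r in sorted(self.spot_map.items()) if r.kind != "empty"
            },
        }

    @classmethod
    def from_manifest(cls, manifest: dict) -> "ChipLayout":
        g = LayoutGeometry(**manifest["geometry"])
        spot_map = {
            i: SpotRole("empty") for i in range(g.rows * g.cols)
        }
        for key, rec in manifest["spots"].items():
            spot_map[int(key)] = SpotRole(rec["kind"], rec.get("probe_id"), rec.get("group_id"))
        return cls(g, spot_map)


def build_layout(panel: MutationPanel, geometry: LayoutGeometry | None = None) -> ChipLayout:
    """Deterministically place the panel on a spot grid.

    Four Cy5 marker spots sit at the grid corners.  Remaining cells are filled
    row-major, group by group: the group's wild-type probe first, then each
    mutant probe, every probe in duplicate, so that a group's spots are
    contiguous on the chip.
    """
    g = geometry or LayoutGeometry()
    n = g.rows * g.cols
    corners = {0, g.cols - 1, (g.rows - 1) * g.cols, n - 1}
    groups = panel.groups
    needed = 2 * (len(panel.entries) + len(groups)) + 4
    if needed > n:
        raise PanelError(
            f"grid {g.rows}x{g.cols} too small: needs {needed} spots, has {n}"
        )
    spot_map: dict[int, SpotRole] = {i: SpotRole("empty") for i in range(n)}
    for c in corners:
        spot_map[c] = SpotRole("marker")
    free = iter(i for i in range(n) if i not in corners)
    for grp in groups:
        for _ in range(2):
            spot_map[next(free)] = SpotRole("wt", grp.wt_probe_id, grp.group_id)
        for e in grp.entries:
            for _ in range(2):
                spot_map[next(free)] = SpotRole("mutant", e.probe_id, grp.group_id)
    return ChipLayout(g, spot_map)
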