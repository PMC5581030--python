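"""Mutation calling from spot quantifications.

The per-spot fluorescence is background-normalized as

    J_m = (I_m - I_0) / (B_m - I_0)

where I_m is the interior intensity of gel pad m, B_m its local background
and I_0 the camera dark current.  Duplicated spots of one probe are averaged,
and within each locus group signals are displayed normalized to the group
maximum.  A mutation is assigned when its probe satisfies J_mut > J_wt and
the signal-to-background requirement J_mut >= 2 (threshold ``min_sbr``); the
printed form of that second criterion divides J by a raw intensity, which is
dimensionally inconsistent — J is itself the background ratio, so the
criterion is read as J_mut >= 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .imaging import QuantTable, SpotQuant
from .panel import ChipLayout, EXCLUSIVE_GENES, MutationPanel, PanelEntry

DEFAULT_MIN_SBR = 2.0


class QCError(ValueError):
    """Raised when a quantification cannot be normalized."""


class LodUndefinedError(RuntimeError):
    """Raised when the 0% dilution shows false positive calls."""


def normalize_signal(i_m: float, b_m: float, i0: float) -> float:
    """Background-normalized spot signal J = (I_m - I_0)/(B_m - I_0)."""
    if b_m <= i0:
        raise QCError(f"background {b_m} does not exceed dark current {i0}")
    return (i_m - i0) / (b_m - i0)


@dataclass(frozen=True)
class GroupSignal:
    group_id: str
    j: dict[str, float] = field(hash=False)           # probe_id -> duplicate-averaged J
    excluded: frozenset[str] = frozenset()            # probes dropped by QC
    wt_probe_id: str = ""

    @property
    def j_wt(self) -> float | None:
        return self.j.get(self.wt_probe_id)

    @property
    def j_norm(self) -> dict[str, float]:
        if not self.j:
            return {}
        m = max(self.j.values())
        if m <= 0:
            return {p: 0.0 for p in self.j}
        return {p: v / m for p, v in self.j.items()}

    def mutant_probes(self) -> dict[str, float]:
        return {p: v for p, v in self.j.items() if p != self.wt_probe_id}


@dataclass(frozen=True)
class Call:
    group_id: str
    verdict: str          # "WT" | "no-call" | probe_id of the called mutation
    entry: PanelEntry | None = None
    margin: float | None = None  # J_mut - J_wt of the called probe
    qc_flags: frozenset[str] = frozenset()

    @property
    def is_mutant(self) -> bool:
        return self.verdict not in ("WT", "no-call")


@dataclass(frozen=True)
class SampleReport:
    sample_id: str
    calls: tuple[Call, ...]
    warnings: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict, hash=False)

    def called_entries(self) -> tuple[PanelEntry, ...]:
        return tuple(c.entry for c in self.calls if c.is_mutant)

    def call_for(self, group_id: str) -> Call:
        for c in self.calls:
            if c.group_id == group_id:
                return c
        raise KeyError(group_id)


def aggregate_groups(quant: QuantTable, layout: ChipLayout,
                     panel: MutationPanel) -> list[GroupSignal]:
    """Average duplicate spots per probe and assemble per-group signals.

    QC-failed duplicates (background at or below dark current, saturated or
    off-grid spots) are dropped; a probe with both duplicates failed is
    excluded from its group and recorded.
    """
    by_index = quant.by_index()
    pairs = layout.duplicate_pairs()
    signals = []
    for grp in panel.groups:
        j: dict[str, float] = {}
        excluded: set[str] = set()
        probe_ids = [grp.wt_probe_id] + [e.probe_id for e in grp.entries]
        for pid in probe_ids:
            values = []
            for idx in pairs[pid]:
                s = by_index.get(idx)
                if s is None:
                    continue
                if s.qc_flags & {"saturated", "off-grid"} or s.b_m <= s.i0:
                    continue
                values.append(normalize_signal(s.i_m, s.b_m, s.i0))
            if values:
                j[pid] = sum(values) / len(values)
            else:
                excluded.add(pid)
        signals.append(GroupSignal(grp.group_id, j, frozenset(excluded), grp.wt_probe_id))
    return signals


def call_group(g: GroupSignal, panel: MutationPanel,
               min_sbr: float = DEFAULT_MIN_SBR) -> Call:
    """Apply the decision rule to one locus group.

    Among mutant probes with J >= ``min_sbr`` and J > J_wt, the probe with
    maximal J is called; with no qualifying probe the group is wild type.  A
    missing/failed WT probe yields a no-call, as does an exact tie between
    two qualifying probes (the rule does not adjudicate ties).
    """
    if g.wt_probe_id in g.excluded or g.j_wt is None:
        return Call(g.group_id, "no-call", qc_flags=frozenset({"wt-probe-failed"}))
    j_wt = g.j_wt
    qualifying = {
        p: v for p, v in g.mutant_probes().items()
        if v >= min_sbr and v > j_wt
    }
    if not qualifying:
        return Call(g.group_id, "WT", margin=None,
                    qc_flags=frozenset({"probes-excluded"}) if g.excluded else frozenset())
    best = max(qualifying.values())
    winners = [p for p, v in qualifying.items() if v == best]
    if len(winners) > 1:
        return Call(g.group_id, "no-call", qc_flags=frozenset({"ambiguous-tie"}))
    probe = winners[0]
    return Call(g.group_id, probe, entry=panel.by_probe_id(probe),
                margin=best - j_wt,
                qc_flags=frozenset({"probes-excluded"}) if g.excluded else frozenset())


def call_sample(groups: list[GroupSignal], panel: MutationPanel,
                sample_id: str = "sample", min_sbr: float = DEFAULT_MIN_SBR,
                provenance: dict | None = None) -> SampleReport:
    """Collect per-group calls and check cross-group consistency.

    Two mutations among the mutually exclusive driver genes (BRAF, NRAS, KIT,
    GNAQ, GNA11) in one sample raise a warning, never an error; MAP2K1/2
    co-occurring with BRAF is expected and not warned.
    """
    calls = tuple(call_group(g, panel, min_sbr) for g in groups)
    warns = []
    mutated_excl_genes = sorted({
        c.entry.gene for c in calls if c.is_mutant and c.entry.gene in EXCLUSIVE_GENES
    })
    if len(mutated_excl_genes) > 1:
        warns.append(
            "mutations in normally mutually exclusive genes: "
            + ", ".join(mutated_excl_genes)
        )
    return SampleReport(sample_id, calls, tuple(warns), provenance or {})


def quantify_and_call(image, layout: ChipLayout, panel: MutationPanel,
                      i0: float | None = None, sample_id: str = "sample",
                      min_sbr: float = DEFAULT_MIN_SBR) -> SampleReport:
    """Convenience: image → quantification → per-group calls."""
    from .imaging import quantify_image

    quant = quantify_image(image, layout, i0=i0, image_id=sample_id)
    groups = aggregate_groups(quant, layout, panel)
    return call_sample(groups, panel, sample_id=sample_id, min_sbr=min_sbr,
                       provenance=dict(quant.meta))


# ---------------------------------------------------------------------------
# Limit of detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LodResult:
    lod_fraction: float | None      # None => above the largest tested fraction
    detection: dict[float, tuple[int, int]] = field(hash=False)  # fraction -> (detected, replicates)
    policy: str = "all"

    @property
    def label(self) -> str:
        if self.lod_fraction is None:
            top = max(self.detection)
            return f"> {top * 100:g}%"
        return f"{self.lod_fraction * 100:g}%"


def estimate_lod(reports: list[tuple[float, SampleReport]], target: PanelEntry,
                 policy: str = "all") -> LodResult:
    """Limit of detection from a dilution series of call reports.

    ``reports`` pairs each report with its true mutant fraction.  The LoD is
    the smallest fraction at which the spiked mutation is called in all
    replicates (policy ``"all"``; ``"majority"`` requires more than half),
    subject to every 0% replicate being wild type in every group — false
    calls at 0% leave the LoD undefined and raise
    :class:`LodUndefinedError`.
    """
    if policy not in ("all", "majority"):
        raise ValueError(f"unknown policy {policy!r}")
    by_fraction: dict[float, list[SampleReport]] = {}
    for f, rep in reports:
        by_fraction.setdefault(f, []).append(rep)
    if len(by_fraction) < 2:
        raise ValueError("need at least two fractions with replicate reports")

    for rep in by_fraction.get(0.0, []):
        false_calls = [c for c in rep.calls if c.is_mutant]
        if false_calls:
            raise LodUndefinedError(
                f"false calls at 0% mutant fraction in {rep.sample_id}: "
                + ", ".join(c.verdict for c in false_calls)
            )

    detection: dict[float, tuple[int, int]] = {}
    for f, reps in sorted(by_fraction.items()):
        hit = sum(1 for r in reps if target in r.called_entries())
        detection[f] = (hit, len(reps))

    lod = None
    for f in sorted(d for d in detection if d > 0):
        hit, n = detection[f]
        ok = (hit == n) if policy == "all" else (hit > n / 2)
        if ok:
            lod = f
            break
    if lod is None:
        warnings.warn("no fraction fully detected; LoD above the tested range",
                      stacklevel=2)
    return LodResult(lod, detection, policy)
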