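"""Cohort frequency accounting, cross-method concordance, and association tests.

Per-sample calls are stored as semicolon-joined ``GENE:c.change`` tokens
(``"WT"`` for a clean wild type, empty for "method not run").  The packaged
fixtures transcribe the study's published per-sample comparison tables
(biochip vs ARMS/Scorpion real-time PCR discordances with clamp+Sanger
arbitration; biochip vs NGS on 25 patients and 6 cell lines) and a
reconstruction of the full 253-patient cohort consistent with the published
marginal counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats

METHODS = ("biochip", "arms", "sanger", "clamp_sanger", "ngs", "consensus")


def parse_calls(token: str | float | None) -> frozenset[str] | None:
    """Parse a call cell: None => method not run; empty set => wild type."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    token = str(token).strip()
    if token == "":
        return None
    if token.upper() == "WT":
        return frozenset()
    return frozenset(t.strip() for t in token.split(";") if t.strip())


def call_genes(calls: frozenset[str]) -> frozenset[str]:
    return frozenset(t.split(":")[0] for t in calls)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _read_packaged(name: str) -> pd.DataFrame:
    text = resources.files("melchip.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), dtype=str, keep_default_na=False)


def load_arms_discordant() -> pd.DataFrame:
    """The ten biochip-vs-ARMS discordant samples with Sanger and
    clamp+Sanger arbitration calls."""
    return _read_packaged("table3_arms_discordant.csv")


def load_ngs_comparison() -> pd.DataFrame:
    """Biochip vs NGS on 25 patient samples and 6 melanoma cell lines."""
    df = _read_packaged("table4_ngs.csv")
    df["is_cell_line"] = df["is_cell_line"].astype(int).astype(bool)
    return df


def load_reference_cohort(seed: int = 20170410) -> pd.DataFrame:
    """Synthetic per-patient reconstruction of the 253-melanoma cohort.

    Only the published marginal counts are deposited, not per-patient data,
    so this table is a reconstruction: biochip per-variant counts, the
    biochip-positive total (177) and wild-type total (76), the additional
    sequencing-only rare variants in the combined ("consensus") calls, the
    sex/subtype margins, and the published mutation-by-covariate
    contingencies are reproduced exactly.  The published marginals force 11
    two-gene patients beyond the 2 stated BRAF+MAP2K1 co-occurrences; the
    extra overlaps are placed on BRAF+KIT (6) and BRAF+GNAQ (3), the pairs
    least constrained by the published exclusivity statements.  Ages are
    drawn deterministically (``seed``) and are plausible, not published.
    """
    rng = np.random.default_rng(seed)
    n = 253
    biochip = [[] for _ in range(n)]  # index 0 = patient 1
    consensus = [[] for _ in range(n)]

    def add(i_patient: int, token: str, biochip_visible: bool = True) -> None:
        if biochip_visible:
            biochip[i_patient - 1].append(token)
        consensus[i_patient - 1].append(token)

    # --- biochip BRAF patients 1..129
    for i in range(1, 112):
        add(i, "BRAF:c.1799T>A")
    for i in range(112, 126):
        add(i, "BRAF:c.1798_1799delGTinsAA")
    for i in range(126, 129):
        add(i, "BRAF:c.1798_1799delGTinsAG")
    add(129, "BRAF:c.1798G>A")
    # stated co-occurrences: MAP2K1 P124S with BRAF V600E
    add(1, "MAP2K1:c.370C>T")
    add(2, "MAP2K1:c.370C>T")
    # marginal-forced overlaps (see docstring)
    for i, tok in zip(range(3, 9), ["KIT:c.1727T>C"] * 5 + ["KIT:c.1924A>G"]):
        add(i, tok)
    add(9, "GNAQ:c.626A>C")
    add(10, "GNAQ:c.626A>C")
    add(11, "GNAQ:c.626A>T")
    # --- NRAS patients 130..174
    for i in range(130, 150):
        add(i, "NRAS:c.181C>A")
    add(130, "NRAS:c.180A>T", biochip_visible=False)  # rare G60G, Sanger only
    for i in range(150, 167):
        add(i, "NRAS:c.182A>G")
    for i in range(167, 170):
        add(i, "NRAS:c.182A>T")
    for i in (170, 171):
        add(i, "NRAS:c.183A>C")
    add(172, "NRAS:c.183A>T")
    add(173, "NRAS:c.37G>C")
    add(174, "NRAS:c.38G>A")
    # --- remaining biochip positives
    add(175, "GNAQ:c.626A>T")
    add(176, "GNA11:c.626A>T")
    add(177, "GNA11:c.626A>T")
    # --- sequencing-only rare variants on biochip-WT patients
    add(178, "BRAF:c.1799_1800delTGinsAC", biochip_visible=False)  # V600D
    add(179, "BRAF:c.1800G>A", biochip_visible=False)              # V600V
    add(180, "BRAF:c.1793C>T", biochip_visible=False)              # A598V
    add(181, "BRAF:c.1794_1795insGTT", biochip_visible=False)      # A598_T599insV
    add(182, "BRAF:c.1797_1798insACA", biochip_visible=False)      # T599_V600insT
    add(183, "GNAQ:c.625_626delCAinsTT", biochip_visible=False)    # rare Q209L

    # --- covariates -----------------------------------------------------
    sex = [None] * n
    for i in range(1, 86):
        sex[i - 1] = "F"
    for i in range(86, 130):
        sex[i - 1] = "M"
    for i in (178, 179):
        sex[i - 1] = "M"
    for i in (180, 181, 182):
        sex[i - 1] = None
    for i in range(130, 149):
        sex[i - 1] = "F"
    for i in range(149, 171):
        sex[i - 1] = "M"
    for i in range(171, 175):
        sex[i - 1] = None
    sex[175 - 1] = "F"
    sex[176 - 1] = "F"
    sex[177 - 1] = "F"
    sex[183 - 1] = "M"
    for i in range(184, 217):
        sex[i - 1] = "F"
    for i in range(217, 245):
        sex[i - 1] = "M"
    # patients 245..253 remain NA

    subtype = [None] * n
    for i in range(130, 137):   # 7 NRAS nodular
        subtype[i - 1] = "nodular"
    for i in range(1, 37):      # 36 further nodular
        subtype[i - 1] = "nodular"
    for i in range(37, 49):     # superficial spreading: 12 BRAF + 12 WT
        subtype[i - 1] = "superficial"
    for i in range(184, 196):
        subtype[i - 1] = "superficial"
    subtype[196 - 1] = "acral"
    for i in range(197, 207):
        subtype[i - 1] = "lentigo"

    def block(assignments: list[tuple[int, int, str]]) -> list:
        col = [None] * n
        for lo, hi, value in assignments:
            for i in range(lo, hi + 1):
                col[i - 1] = value
        return col

    location = block([(1, 82, "trunk"), (83, 105, "upper limb"),
                      (106, 171, "lower limb"), (172, 201, "head and neck")])
    stage = block([(1, 1, "0"), (2, 15, "I"), (16, 59, "II"),
                   (60, 76, "III"), (77, 81, "IV")])
    breslow = block([(1, 26, "<=1"), (27, 45, "1.01-2"),
                     (46, 73, "2.01-4"), (74, 117, ">4")])
    clark = block([(1, 3, "I"), (4, 16, "II"), (17, 81, "III"),
                   (82, 99, "IV"), (100, 119, "V")])
    ulceration = block([(1, 68, "yes"), (69, 118, "no")])

    braf_any = {i for i in range(1, n + 1)
                if any(t.startswith("BRAF") for t in consensus[i - 1])}
    age = [round(float(np.clip(rng.normal(52.7 if i in braf_any else 55.1,
                                          14.2 if i in braf_any else 18.8),
                               1.0, 88.0)), 1)
           for i in range(1, n + 1)]

    return pd.DataFrame({
        "sample_id": [f"P{i:03d}" for i in range(1, n + 1)],
        "biochip": [";".join(c) if c else "WT" for c in biochip],
        "consensus": [";".join(c) if c else "WT" for c in consensus],
        "sex": sex, "age": age, "subtype": subtype, "location": location,
        "stage": stage, "breslow": breslow, "clark": clark,
        "ulceration": ulceration,
    })


# ---------------------------------------------------------------------------
# Frequency accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FreqTable:
    method: str
    n: int
    gene_counts: dict[str, int] = field(hash=False)      # patients with >=1 variant
    variant_counts: dict[str, int] = field(hash=False)   # variant instances
    n_positive: int = 0

    @property
    def n_wt(self) -> int:
        return self.n - self.n_positive

    @property
    def positive_rate_pct(self) -> float:
        return round(100.0 * self.n_positive / self.n, 1)

    def gene_pct(self, gene: str) -> float:
        return round(100.0 * self.gene_counts.get(gene, 0) / self.n, 1)

    def variant_share_pct(self, token: str) -> float:
        """Share of one variant among all variant instances of its gene."""
        gene = token.split(":")[0]
        total = sum(c for t, c in self.variant_counts.items()
                    if t.split(":")[0] == gene)
        return round(100.0 * self.variant_counts.get(token, 0) / total, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.gene_counts):
            rows.append({"level": "gene", "name": gene,
                         "count": self.gene_counts[gene],
                         "pct_of_cohort": self.gene_pct(gene)})
        for tok in sorted(self.variant_counts):
            rows.append({"level": "variant", "name": tok,
                         "count": self.variant_counts[tok],
                         "pct_of_cohort": round(100.0 * self.variant_counts[tok] / self.n, 1)})
        return pd.DataFrame(rows)


def summarize_cohort(records: pd.DataFrame, method: str) -> FreqTable:
    """Per-gene and per-variant counts for one method over a cohort table."""
    if records.empty:
        raise ValueError("empty cohort")
    if method not in records.columns:
        raise ValueError(f"unknown method {method!r}")
    gene_counts: dict[str, int] = {}
    variant_counts: dict[str, int] = {}
    n_positive = 0
    n = 0
    for token in records[method]:
        calls = parse_calls(token)
        if calls is None:
            continue
        n += 1
        if calls:
            n_positive += 1
        for gene in call_genes(calls):
            gene_counts[gene] = gene_counts.get(gene, 0) + 1
        for tok in calls:
            variant_counts[tok] = variant_counts.get(tok, 0) + 1
    return FreqTable(method, n, gene_counts, variant_counts, n_positive)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceRecord:
    sample_id: str
    calls_a: frozenset[str]
    calls_b: frozenset[str]
    is_cell_line: bool = False

    @property
    def agree(self) -> bool:
        return self.calls_a == self.calls_b

    @property
    def a_only(self) -> frozenset[str]:
        return self.calls_a - self.calls_b

    @property
    def b_only(self) -> frozenset[str]:
        return self.calls_b - self.calls_a


@dataclass(frozen=True)
class ConcordanceTable:
    method_a: str
    method_b: str
    records: tuple[ConcordanceRecord, ...]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def discordant(self) -> tuple[ConcordanceRecord, ...]:
        return tuple(r for r in self.records if not r.agree)

    @property
    def n_discordant(self) -> int:
        return len(self.discordant)

    def samples_with_a_only(self, genes: set[str] | None = None,
                            include_cell_lines: bool = True) -> tuple[str, ...]:
        out = []
        for r in self.records:
            if r.is_cell_line and not include_cell_lines:
                continue
            extra = r.a_only
            if genes is not None:
                extra = frozenset(t for t in extra if t.split(":")[0] in genes)
            if extra:
                out.append(r.sample_id)
        return tuple(out)

    def samples_with_b_only(self, genes: set[str] | None = None,
                            include_cell_lines: bool = True) -> tuple[str, ...]:
        flipped = ConcordanceTable(
            self.method_b, self.method_a,
            tuple(ConcordanceRecord(r.sample_id, r.calls_b, r.calls_a, r.is_cell_line)
                  for r in self.records),
        )
        return flipped.samples_with_a_only(genes, include_cell_lines)


def compare_methods(records: pd.DataFrame, method_a: str, method_b: str,
                    panel=None, restrict_to_panel: bool = False) -> ConcordanceTable:
    """Pairwise call-set comparison between two methods.

    A sample is discordant when the two call sets differ — optionally after
    restricting both sides to panel-representable variants.
    """
    panel_tokens = None
    if restrict_to_panel:
        if panel is None:
            from .panel import load_default_panel

            panel = load_default_panel()
        panel_tokens = {e.probe_id for e in panel.entries}
    recs = []
    for row in records.itertuples():
        a = parse_calls(getattr(row, method_a))
        b = parse_calls(getattr(row, method_b))
        if a is None or b is None:
            continue
        if panel_tokens is not None:
            a = frozenset(t for t in a if t in panel_tokens)
            b = frozenset(t for t in b if t in panel_tokens)
        recs.append(ConcordanceRecord(
            str(getattr(row, "patient", getattr(row, "sample_id", row.Index))),
            a, b, bool(getattr(row, "is_cell_line", False)),
        ))
    if not recs:
        raise ValueError("no sample has calls from both methods")
    return ConcordanceTable(method_a, method_b, tuple(recs))


@dataclass(frozen=True)
class ResolutionSummary:
    confirms_a: int
    confirms_b: int
    confirms_neither: int
    unresolved: int
    labels: dict[str, str] = field(hash=False)


def resolve_discordance(table: ConcordanceTable, records: pd.DataFrame,
                        arbiter_method: str) -> ResolutionSummary:
    """Label each discordant sample by exact call-set match with an arbiter.

    ``confirms-neither`` covers arbiters reporting variants matching neither
    method — typically rare off-panel mutations the chip cannot see.
    """
    id_col = "patient" if "patient" in records.columns else "sample_id"
    arb = {str(r[id_col]): parse_calls(r[arbiter_method])
           for _, r in records.iterrows()}
    labels: dict[str, str] = {}
    counts = {"confirms_a": 0, "confirms_b": 0, "confirms_neither": 0, "unresolved": 0}
    for rec in table.discordant:
        a_call = arb.get(rec.sample_id)
        if a_call is None:
            labels[rec.sample_id] = "unresolved"
        elif a_call == rec.calls_a:
            labels[rec.sample_id] = "confirms_a"
        elif a_call == rec.calls_b:
            labels[rec.sample_id] = "confirms_b"
        else:
            labels[rec.sample_id] = "confirms_neither"
        counts[labels[rec.sample_id]] += 1
    return ResolutionSummary(counts["confirms_a"], counts["confirms_b"],
                             counts["confirms_neither"], counts["unresolved"], labels)


# ---------------------------------------------------------------------------
# Association statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    pvalue: float
    test: str
    table: tuple | None = None
    n: int = 0


def association_tests(records: pd.DataFrame, covariate: str, gene: str,
                      method: str = "consensus", test: str = "fisher",
                      levels: tuple[str, str] | None = None) -> AssociationResult:
    """Association between mutation status of one gene and a covariate.

    Categorical covariates give a 2x2 table tested with the two-sided Fisher
    exact test by default (``test`` also accepts ``"chi2_yates"`` and plain
    ``"chi2"``); the continuous covariate ``age`` uses the two-sided
    Mann-Whitney U.  Records with a missing covariate are excluded pairwise.
    """
    mutated = []
    values = []
    for _, row in records.iterrows():
        calls = parse_calls(row[method])
        cov = row[covariate]
        if calls is None or cov is None or (isinstance(cov, float) and np.isnan(cov)):
            continue
        mutated.append(gene in call_genes(calls))
        values.append(cov)
    if covariate == "age" or test == "mannwhitney":
        x = [v for v, m in zip(values, mutated) if m]
        y = [v for v, m in zip(values, mutated) if not m]
        if not x or not y:
            raise ValueError("degenerate grouping: one side empty")
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return AssociationResult(float(stat), float(p), "mannwhitney", n=len(values))

    if levels is None:
        levels = tuple(pd.unique(values))  # type: ignore[assignment]
    if len(levels) != 2:
        raise ValueError(f"need exactly two covariate levels, got {levels}")
    table = np.zeros((2, 2), dtype=int)
    for v, m in zip(values, mutated):
        if v not in levels:
            continue
        table[levels.index(v) if isinstance(levels, list) else list(levels).index(v),
              0 if m else 1] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table {table.tolist()}")
    if test == "fisher":
        stat, p = stats.fisher_exact(table, alternative="two-sided")
    elif test == "chi2_yates":
        stat, p, *_ = stats.chi2_contingency(table, correction=True)
    elif test == "chi2":
        stat, p, *_ = stats.chi2_contingency(table, correction=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return AssociationResult(float(stat), float(p), test,
                             tuple(map(tuple, table.tolist())), int(table.sum()))
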