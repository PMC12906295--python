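"""Tolerance registry, pass/fail evaluation and acceptance reporting.

The default registry mirrors the manufacturer/guideline tolerances for a
0.35 T MR-Linac acceptance test.  A printed "<" tolerance is strict, while
"<=" / "within +-" tolerances are inclusive.  Couch attenuation carries two
entries (the +-3% method tolerance and the stricter +-1% results
tolerance); the field output factor has no manufacturer tolerance and is
reported informationally with an n/a verdict.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

__all__ = [
    "ToleranceSpec",
    "TestResult",
    "AcceptanceReport",
    "evaluate",
    "build_report",
    "render",
    "default_registry",
    "load_registry",
    "save_registry",
]

COMPARATORS = ("abs_le", "abs_lt", "le", "lt", "ge", "gt", "within_range", "none")
CATEGORIES = ("mechanical", "dosimetric", "mri")


@dataclass
class ToleranceSpec:
    metric_id: str
    comparator: str
    threshold: float | tuple[float, float] | None
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.comparator == "within_range":
            lo, hi = self.threshold  # type: ignore[misc]
            if not float(lo) < float(hi):
                raise ValueError("range threshold must be (lo, hi) with lo < hi")
            self.threshold = (float(lo), float(hi))
        elif self.comparator != "none":
            self.threshold = float(self.threshold)  # type: ignore[arg-type]


def evaluate(value: float, tol: ToleranceSpec) -> str:
    """Apply a tolerance comparator to a value: 'pass', 'fail' or 'n/a'.

    Boundary values pass for the inclusive (<=, >=, within-range)
    comparators and fail for the strict (<, >) ones.
    """
    c, t = tol.comparator, tol.threshold
    if c == "none":
        return "n/a"
    if c == "abs_le":
        return "pass" if abs(value) <= t else "fail"
    if c == "abs_lt":
        return "pass" if abs(value) < t else "fail"
    if c == "le":
        return "pass" if value <= t else "fail"
    if c == "lt":
        return "pass" if value < t else "fail"
    if c == "ge":
        return "pass" if value >= t else "fail"
    if c == "gt":
        return "pass" if value > t else "fail"
    lo, hi = t  # within_range
    return "pass" if lo <= value <= hi else "fail"


@dataclass
class TestResult:
    __test__ = False  # not a pytest collectible despite the name

    metric_id: str
    value: float
    tolerance: ToleranceSpec
    category: str = "mechanical"
    verdict: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        expected = evaluate(self.value, self.tolerance)
        if self.verdict is None:
            self.verdict = expected
        elif self.verdict != expected:
            raise ValueError(
                f"verdict {self.verdict!r} inconsistent with comparator (expected {expected!r})"
            )


@dataclass
class AcceptanceReport:
    results: list[TestResult]
    metadata: dict = field(default_factory=dict)

    @property
    def groups(self) -> dict[str, list[TestResult]]:
        return {c: [r for r in self.results if r.category == c] for c in CATEGORIES}

    @property
    def summary(self) -> dict[str, int]:
        counts = {"pass": 0, "fail": 0, "n/a": 0}
        for r in self.results:
            counts[r.verdict] += 1
        counts["total"] = len(self.results)
        return counts


def build_report(results: Sequence[TestResult], metadata: Mapping | None = None) -> AcceptanceReport:
    """Assemble results into a report with stable ordering and group counts."""
    results = list(results)
    if not results:
        raise ValueError("cannot build a report from an empty result list")
    ids = [r.metric_id for r in results]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate metric ids: {sorted(dupes)}")
    ordered = sorted(results, key=lambda r: (CATEGORIES.index(r.category), r.metric_id))
    return AcceptanceReport(ordered, dict(metadata or {}))


def _result_dict(r: TestResult) -> dict:
    d = asdict(r)
    thr = d["tolerance"]["threshold"]
    if isinstance(thr, tuple):
        d["tolerance"]["threshold"] = list(thr)
    return d


def render(report: AcceptanceReport, format: str = "json") -> str:
    """Render a report as JSON (lossless round-trip) or Markdown."""
    if format == "json":
        return json.dumps(
            {
                "metadata": report.metadata,
                "summary": report.summary,
                "results": [_result_dict(r) for r in report.results],
            },
            indent=2,
            sort_keys=True,
        )
    if format != "markdown":
        raise ValueError("format must be 'json' or 'markdown'")
    lines = ["# MR-Linac acceptance report", ""]
    s = report.summary
    lines.append(f"**{s['pass']} pass / {s['fail']} fail / {s['n/a']} n/a** of {s['total']} metrics")
    for cat, results in report.groups.items():
        if not results:
            continue
        lines += ["", f"## {cat.capitalize()}", "",
                  "| metric | value | tolerance | verdict | source |",
                  "|---|---|---|---|---|"]
        for r in results:
            t = r.tolerance
            tdesc = "n/a" if t.comparator == "none" else f"{t.comparator} {t.threshold} {t.units}"
            lines.append(f"| {r.metric_id} | {r.value:g} | {tdesc} | {r.verdict} | {t.source} |")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> AcceptanceReport:
    """Inverse of ``render(report, 'json')``."""
    raw = json.loads(text)
    results = []
    for d in raw["results"]:
        td = d["tolerance"]
        thr = td["threshold"]
        tol = ToleranceSpec(td["metric_id"], td["comparator"],
                            tuple(thr) if isinstance(thr, list) else thr,
                            td["units"], td["source"])
        results.append(TestResult(d["metric_id"], d["value"], tol,
                                  d["category"], d["verdict"], d["provenance"]))
    return AcceptanceReport(results, raw.get("metadata", {}))


# ----------------------------------------------------------------------
# default tolerance registry
# ----------------------------------------------------------------------
def default_registry() -> dict[str, ToleranceSpec]:
    """Manufacturer/guideline tolerances for the 0.35 T MR-Linac acceptance."""
    entries = [
        # mechanical
        ("starshot_radius_mm", "abs_le", 1.0, "mm", "radiation isocenter within +-1 mm"),
        ("isocenter_coincidence_mm", "abs_le", 1.0, "mm", "laser/RT/MRI isocenter coincidence +-1 mm"),
        ("field_size_diff_cm", "abs_le", 0.2, "cm", "measured vs TPS field size +-2 mm"),
        ("mlc_leakage_avg_pct", "lt", 0.375, "%", "average MLC transmission < 0.375%"),
        ("mlc_leakage_max_pct", "lt", 1.0, "%", "maximum MLC transmission (1 cm^2) < 1%"),
        ("mlc_leaf_shift_mm", "abs_le", 2.0, "mm", "MLC linearity/position +-2 mm"),
        # dosimetric
        ("flatness_diff_pct", "abs_le", 2.0, "%", "point flatness M-TPS within +-2%"),
        ("symmetry_pct", "abs_le", 2.0, "%", "symmetry of +-OAP measured points within +-2%"),
        ("penumbra_diff_mm", "abs_le", 1.0, "mm", "penumbra measured vs TPS <= 1 mm"),
        ("couch_attenuation_deviation_pct", "abs_le", 1.0, "%", "couch attenuation results tolerance +-1%"),
        ("couch_attenuation_method_pct", "abs_le", 3.0, "%", "couch attenuation method tolerance +-3%"),
        ("fof_diff_pct", "none", None, "%", "field output factor: no manufacturer tolerance"),
        # mri
        ("b0_homogeneity_ppm", "le", 5.0, "ppm", "peak-to-peak inhomogeneity below 5 ppm / 24 cm DSV"),
        ("central_frequency_hz", "within_range", (14_686_760.0, 14_716_760.0), "Hz",
         "f0 = 14.70176 +- 0.015 MHz"),
        ("snr_body", "ge", 12.0, "", "body coil SNR >= 12"),
        ("snr_surface_transverse_sagittal", "gt", 30.0, "", "torso/head-neck SNR > 30"),
        ("snr_surface_coronal", "gt", 25.0, "", "torso/head-neck coronal SNR > 25"),
        ("uniformity_body_pct", "ge", 60.0, "%", "body coil uniformity >= 60%"),
        ("uniformity_surface_pct", "gt", 50.0, "%", "torso/head-neck uniformity > 50%"),
        ("spatial_integrity_mm", "lt", 2.0, "mm", "spatial accuracy < 2 mm (20-35 cm DSV)"),
        ("spatial_integrity_20cm_mm", "lt", 1.0, "mm", "spatial accuracy < 1 mm (20 cm DSV)"),
        ("acr_psg", "lt", 0.025, "", "percent signal ghosting < 0.025"),
        ("acr_piu_pct", "gt", 87.5, "%", "percent integral uniformity > 87.5%"),
        ("acr_slice_thickness_mm", "within_range", (4.3, 5.7), "mm", "slice thickness 5.0 +- 0.7 mm"),
        ("acr_slice_position_mm", "le", 5.0, "mm", "slice position accuracy <= 5 mm"),
    ]
    return {mid: ToleranceSpec(mid, cmp_, thr, units, src)
            for mid, cmp_, thr, units, src in entries}


def save_registry(registry: Mapping[str, ToleranceSpec], path) -> None:
    data = {
        mid: {
            "comparator": t.comparator,
            "threshold": list(t.threshold) if isinstance(t.threshold, tuple) else t.threshold,
            "units": t.units,
            "source": t.source,
        }
        for mid, t in registry.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_registry(path) -> dict[str, ToleranceSpec]:
    """Load a site-specific YAML registry, overriding defaults per metric."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    registry = default_registry()
    for mid, spec in data.items():
        thr = spec.get("threshold")
        if isinstance(thr, list):
            thr = tuple(thr)
        registry[mid] = ToleranceSpec(
            mid, spec["comparator"], thr, spec.get("units", ""), spec.get("source", "")
        )
    return registry
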