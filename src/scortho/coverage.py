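"""Completeness of query gene sets against a single-copy reference.

The detection step (mapping query proteins or ESTs to reference groups by
similarity search) happens upstream with external tools; this module
consumes the resulting per-species assignment tables and reports, for each
species, how many reference single-copy groups were found and the
percentage of the reference covered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "CoverageError",
    "SpeciesCoverage",
    "CoverageReport",
    "completeness",
    "saturation_curve",
    "read_assignments_tsv",
    "read_reference_ids",
]


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesCoverage:
    n_found: int
    n_missing: int
    percent_found: float  # 0..100, one decimal place


@dataclass
class CoverageReport:
    reference_size: int
    per_species: dict[str, SpeciesCoverage]
    mean_percent: float

    def to_json_dict(self) -> dict:
        return {
            "reference_size": self.reference_size,
            "mean_percent": self.mean_percent,
            "per_species": {
                species: {
                    "n_found": cov.n_found,
                    "n_missing": cov.n_missing,
                    "percent_found": cov.percent_found,
                }
                for species, cov in sorted(self.per_species.items())
            },
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_json_dict(), **kwargs)

    def to_tsv(self) -> str:
        lines = ["species\tn_found\tn_missing\tpercent_found"]
        for species, cov in sorted(self.per_species.items()):
            lines.append(f"{species}\t{cov.n_found}\t{cov.n_missing}\t"
                         f"{cov.percent_found}")
        return "\n".join(lines) + "\n"


def completeness(assignments: Mapping[str, Iterable[str]],
                 reference: Iterable[str]) -> CoverageReport:
    """Per-species found/missing counts against the reference group set.

    Repeated assignment entries count once (set semantics).  Assignments
    referencing group ids outside the reference are rejected, listing the
    offending ids.
    """
    reference = frozenset(reference)
    if not reference:
        raise CoverageError("reference group set is empty")
    unknown = sorted({gid for groups in assignments.values()
                      for gid in groups} - reference)
    if unknown:
        raise CoverageError(
            "assignments reference unknown group ids: " + ", ".join(unknown))
    per_species: dict[str, SpeciesCoverage] = {}
    for species, groups in assignments.items():
        found = len(set(groups))
        percent = round(100.0 * found / len(reference), 1)
        per_species[species] = SpeciesCoverage(
            n_found=found, n_missing=len(reference) - found,
            percent_found=percent)
    percents = [cov.percent_found for cov in per_species.values()]
    mean = round(sum(percents) / len(percents), 1) if percents else 0.0
    return CoverageReport(reference_size=len(reference),
                          per_species=per_species, mean_percent=mean)


def saturation_curve(points: Iterable[tuple[float, int]]
                     ) -> list[tuple[float, int]]:
    """Order (dataset size, n found) points by size for plotting."""
    points = list(points)
    if not points:
        raise CoverageError("saturation_curve needs at least one point")
    return sorted(points, key=lambda p: (p[0], p[1]))


def read_assignments_tsv(path) -> dict[str, set[str]]:
    """Read ``species <TAB> group_id`` rows into per-species id sets."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise CoverageError(
                    f"{path}:{lineno}: expected 'species<TAB>group_id'")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def read_reference_ids(path) -> set[str]:
    """Read reference group ids, one per line."""
    with open(path, encoding="utf-8") as handle:
        return {line.strip() for line in handle
                if line.strip() and not line.startswith("#")}
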