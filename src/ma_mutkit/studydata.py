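"""Treatment-level mutation counts from the multigenerational thermal MA study.

These are the published aggregate inputs for the rate arithmetic on real
data: per-treatment de novo mutation counts from five sequenced plants per
arm of an *Arabidopsis thaliana* mutation-accumulation experiment run under
Control (23/18 C), Warming (28/23 C), and Heat (32/27 C) regimes — three
single-seed-descent line arms sequenced at generation 10 and three ~35-plant
population arms sequenced at generations 16 (Control), 19 (Warming), and
22 (Heat). On average 116 Mb (96.9%) of the reference genome was accessible
for variant calling; that figure is used as the accessible-site denominator
for every lineage (per-lineage accessibility varies by a few percent, which
is the resolution limit of rates recomputed from these aggregates).
"""

from __future__ import annotations

from dataclasses import dataclass

ACCESSIBLE_SITES = 116_000_000  # average accessible bases per sample
N_SAMPLES = 5  # sequenced plants per treatment arm


@dataclass(frozen=True)
class TreatmentCounts:
    label: str
    design: str  # line | population
    generations: int
    n_snv: int
    n_indel: int
    n_del: int | None = None  # deletion/insertion split where reported
    n_ins: int | None = None

    @property
    def n_total(self) -> int:
        return self.n_snv + self.n_indel


LINES = {
    "Control_D10": TreatmentCounts("Control_D10", "line", 10, 31, 8),
    "Heat_E10": TreatmentCounts("Heat_E10", "line", 10, 69, 29, n_del=25, n_ins=4),
    "Warming_F10": TreatmentCounts("Warming_F10", "line", 10, 54, 20, n_del=17, n_ins=3),
}

POPULATIONS = {
    "Control_A16": TreatmentCounts("Control_A16", "population", 16, 60, 10),
    "Heat_B22": TreatmentCounts("Heat_B22", "population", 22, 130, 53, n_del=42, n_ins=11),
    "Warming_C19": TreatmentCounts("Warming_C19", "population", 19, 88, 35, n_del=22, n_ins=13),
}

ALL_ARMS = {**LINES, **POPULATIONS}
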