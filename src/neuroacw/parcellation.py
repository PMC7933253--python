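"""Parcellation metadata and core-periphery (CP) division schemes.

Two parcellation templates are modelled: a 200-region / 7-network
Schaefer-style template and a 360-region / 12-network Ji-style template.
Each region carries its functional network and an anterior-posterior
coordinate ``y_mm`` (larger = more anterior).

Three CP labellings are supported:

* **SCP** (Schaefer/Margulies): periphery = sensory/attention networks
  (Visual, Somatomotor, Dorsal Attention, Salience); core = Limbic, FPC,
  DMN. No exclusions.
* **JCP** (Ji/Ito, unimodal-transmodal): periphery = Visual1, Visual2,
  Auditory, Somatomotor; core = the remaining eight networks.
* **RCP** (restricted Ji/Ito): periphery as JCP, core restricted to
  Cingulo Opercular, FPC and DMN; the other transmodal networks are
  excluded from the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SCHAEFER_NETWORKS",
    "JI_NETWORKS",
    "TEMPLATE_NETWORKS",
    "CPDivisionSpec",
    "builtin_divisions",
    "assign_cp",
    "load_region_table",
    "save_region_table",
    "validate_region_table",
]

SCHAEFER_NETWORKS = (
    "Visual",
    "Somatomotor",
    "Dorsal Attention",
    "Salience",
    "Limbic",
    "FPC",
    "DMN",
)

JI_NETWORKS = (
    "Visual1",
    "Visual2",
    "Auditory",
    "Somatomotor",
    "Dorsal Attention",
    "Posterior Multimodal",
    "Ventral Multimodal",
    "Orbito Affective",
    "Language",
    "Cingulo Opercular",
    "FPC",
    "DMN",
)

TEMPLATE_NETWORKS: dict[str, tuple[str, ...]] = {
    "schaefer": SCHAEFER_NETWORKS,
    "ji": JI_NETWORKS,
}

REGION_TABLE_COLUMNS = ("region_id", "name", "template", "network", "y_mm")


@dataclass(frozen=True)
class CPDivisionSpec:
    """A core/periphery/excluded partition of a template's networks."""

    name: str
    template: str
    periphery_networks: frozenset[str]
    core_networks: frozenset[str]
    excluded_networks: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        networks = set(TEMPLATE_NETWORKS[self.template])
        sets = (self.periphery_networks, self.core_networks, self.excluded_networks)
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError(f"{self.name}: periphery/core/excluded sets overlap")
        if set().union(*sets) != networks:
            missing = networks - set().union(*sets)
            extra = set().union(*sets) - networks
            raise ValueError(
                f"{self.name}: network sets do not partition the {self.template} "
                f"template (missing={sorted(missing)}, unknown={sorted(extra)})"
            )

    def label(self, network: str) -> str:
        if network in self.periphery_networks:
            return "periphery"
        if network in self.core_networks:
            return "core"
        if network in self.excluded_networks:
            return "excluded"
        raise ValueError(f"network {network!r} unknown to division {self.name}")


def builtin_divisions() -> dict[str, CPDivisionSpec]:
    """The three CP divisions: SCP, JCP and RCP."""
    jcp_periphery = frozenset({"Visual1", "Visual2", "Auditory", "Somatomotor"})
    scp = CPDivisionSpec(
        name="SCP",
        template="schaefer",
        periphery_networks=frozenset(
            {"Visual", "Somatomotor", "Dorsal Attention", "Salience"}
        ),
        core_networks=frozenset({"Limbic", "FPC", "DMN"}),
    )
    jcp = CPDivisionSpec(
        name="JCP",
        template="ji",
        periphery_networks=jcp_periphery,
        core_networks=frozenset(JI_NETWORKS) - jcp_periphery,
    )
    rcp_core = frozenset({"Cingulo Opercular", "FPC", "DMN"})
    rcp = CPDivisionSpec(
        name="RCP",
        template="ji",
        periphery_networks=jcp_periphery,
        core_networks=rcp_core,
        excluded_networks=frozenset(JI_NETWORKS) - jcp_periphery - rcp_core,
    )
    return {"SCP": scp, "JCP": jcp, "RCP": rcp}


def validate_region_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check columns, network membership and region-id uniqueness."""
    missing = set(REGION_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    if table["region_id"].duplicated().any():
        dupes = table.loc[table["region_id"].duplicated(), "region_id"].tolist()
        raise ValueError(f"duplicate region_id values: {dupes}")
    for template, group in table.groupby("template"):
        if template not in TEMPLATE_NETWORKS:
            raise ValueError(f"unknown template {template!r}")
        bad = set(group["network"]) - set(TEMPLATE_NETWORKS[template])
        if bad:
            rows = group[group["network"].isin(bad)]
            raise ValueError(
                f"unknown networks for template {template!r}: {sorted(bad)} "
                f"(regions {rows['region_id'].tolist()[:5]})"
            )
    return table


def assign_cp(regions: pd.DataFrame, spec: CPDivisionSpec) -> pd.DataFrame:
    """Label every region core/periphery/excluded under ``spec``.

    Excluded regions are kept in the returned table (marked ``excluded``)
    so downstream stages can drop them explicitly.
    """
    validate_region_table(regions)
    templates = set(regions["template"])
    if templates != {spec.template}:
        raise ValueError(
            f"division {spec.name} is defined on template {spec.template!r}, "
            f"table has {sorted(templates)}"
        )
    out = regions.copy()
    out["cp"] = [spec.label(net) for net in out["network"]]
    return out


def save_region_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_region_table(table)
    table.to_csv(path, sep="\t", index=False)


def load_region_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed region table {path}: {err}") from err
    return validate_region_table(table)
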