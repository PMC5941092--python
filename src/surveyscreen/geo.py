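"""Offline geographic lookup: IP /24 prefixes and 3-digit zip prefixes to regions.

No live geolocation service is ever called. A lookup is a total function:
unknown keys map to ``"unknown"``, and a rule can never strike on an
unverifiable location. The bundled table is synthetic — fictional /24
prefixes drawn from the 100.64.0.0/10 shared address space, mapped to US
state codes alongside real-shaped 3-digit zip prefixes — and exists so the
simulator and the geo-consistency rule share one vocabulary without any
external data.
"""
from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

UNKNOWN = "unknown"

# region -> (utc_offset_hours, zip3 prefixes, ip /24 prefixes). Synthetic.
REGION_SPECS: dict[str, tuple[int, list[str], list[str]]] = {}
_STATES = [
    ("NY", -5, ["100", "101", "112"]),
    ("MA", -5, ["021", "022", "023"]),
    ("PA", -5, ["150", "152", "191"]),
    ("IL", -6, ["601", "606", "607"]),
    ("TX", -6, ["750", "770", "787"]),
    ("MN", -6, ["551", "553", "554"]),
    ("CO", -7, ["802", "803", "805"]),
    ("AZ", -7, ["850", "852", "853"]),
    ("CA", -8, ["900", "920", "941"]),
    ("WA", -8, ["980", "981", "982"]),
]
for _i, (_state, _off, _zips) in enumerate(_STATES):
    REGION_SPECS[_state] = (
        _off,
        _zips,
        [f"100.64.{4 * _i + _j}" for _j in range(4)],
    )


@dataclass
class GeoTable:
    """Mapping of IP /24 prefixes and zip3 prefixes to one region vocabulary."""

    ip_prefix_to_region: dict[str, str] = field(default_factory=dict)
    zip3_to_region: dict[str, str] = field(default_factory=dict)

    def region_for_ip(self, ip: Union[str, None]) -> str:
        if not ip:
            return UNKNOWN
        parts = ip.split(".")
        if len(parts) != 4:
            return UNKNOWN
        return self.ip_prefix_to_region.get(".".join(parts[:3]), UNKNOWN)

    def region_for_zip(self, zip_code: Union[str, None]) -> str:
        if not zip_code or len(zip_code) < 3:
            return UNKNOWN
        return self.zip3_to_region.get(zip_code[:3], UNKNOWN)


def default_geo_table() -> GeoTable:
    """The bundled synthetic table used by the simulator and examples."""
    table = GeoTable()
    for region, (_off, zips, ips) in REGION_SPECS.items():
        for z in zips:
            table.zip3_to_region[z] = region
        for p in ips:
            table.ip_prefix_to_region[p] = region
    return table


def region_utc_offset(region: str) -> dt.timezone:
    """Fixed UTC offset for a bundled region (DST deliberately ignored)."""
    off, _, _ = REGION_SPECS[region]
    return dt.timezone(dt.timedelta(hours=off))


def load_geo_table(path: Union[str, Path]) -> GeoTable:
    """Read a geo table CSV with columns ``kind`` (ip24|zip3), ``key``, ``region``."""
    table = GeoTable()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"kind", "key", "region"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"geo table must have columns {sorted(required)}")
        for row in reader:
            if row["kind"] == "ip24":
                table.ip_prefix_to_region[row["key"]] = row["region"]
            elif row["kind"] == "zip3":
                table.zip3_to_region[row["key"]] = row["region"]
            else:
                raise ValueError(f"unknown geo table kind {row['kind']!r}")
    return table


def write_geo_table(table: GeoTable, path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "key", "region"])
        for key, region in sorted(table.ip_prefix_to_region.items()):
            writer.writerow(["ip24", key, region])
        for key, region in sorted(table.zip3_to_region.items()):
            writer.writerow(["zip3", key, region])
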