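"""Bundled reference data: the ten-complex BRD4-1 ITC benchmark table."""

from __future__ import annotations

from importlib import resources

from .io_formats import ThermoRecord, read_benchmark_table


def itc_benchmark() -> list[ThermoRecord]:
    """The ten-complex BRD4-1 ITC benchmark (dH, TdS, dG in kcal/mol)."""
    text = resources.files("bindcalor.data").joinpath("itc_benchmark.csv").read_text()
    return read_benchmark_table(text)
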