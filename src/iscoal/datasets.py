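"""Bundled example datasets."""

from importlib import resources

from .data import K69Dataset, parse_dataset

__all__ = ["table1"]


def table1() -> K69Dataset:
    """The five-sequence, four-site worked example.

    Four distinct haplotypes (a1..a4) over four segregating sites with
    multiplicities (2, 1, 1, 1); a standard small dataset for exercising
    the exact recursion and the samplers by hand.
    """
    text = resources.files("iscoal.fixtures").joinpath("table1.xml").read_text()
    return parse_dataset(text, format="xml", name="table1")
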