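"""Uniform access to reference sequence from several container types.

The classifier and scanners only ever need two primitives — fetch a slice and
report a contig length — so they accept any of:

* a :class:`pysam.FastaFile` (indexed FASTA on disk),
* a ``dict`` mapping contig name -> sequence string,
* a bare string (treated as a single anonymous contig).
"""

from __future__ import annotations

from typing import Mapping, Union

__all__ = ["RefView", "as_refview"]


class RefView:
    """Normalize a reference source to ``get(chrom, start, end)`` / ``length(chrom)``.

    Slices are clipped to contig bounds; returned sequence is uppercased.
    """

    def __init__(self, source) -> None:
        self._source = source
        self._kind = self._detect(source)

    @staticmethod
    def _detect(source) -> str:
        if hasattr(source, "fetch") and hasattr(source, "get_reference_length"):
            return "pysam"
        if isinstance(source, Mapping):
            return "dict"
        if isinstance(source, str):
            return "str"
        raise TypeError(f"unsupported reference source: {type(source)!r}")

    def contigs(self):
        if self._kind == "pysam":
            return list(self._source.references)
        if self._kind == "dict":
            return list(self._source)
        return [None]

    def length(self, chrom: Union[str, None]) -> int:
        if self._kind == "pysam":
            return self._source.get_reference_length(chrom)
        if self._kind == "dict":
            return len(self._source[chrom])
        return len(self._source)

    def get(self, chrom: Union[str, None], start: int, end: int) -> str:
        n = self.length(chrom)
        start, end = max(0, start), min(n, end)
        if start >= end:
            return ""
        if self._kind == "pysam":
            return self._source.fetch(chrom, start, end).upper()
        if self._kind == "dict":
            return self._source[chrom][start:end].upper()
        return self._source[start:end].upper()


def as_refview(source) -> RefView:
    return source if isinstance(source, RefView) else RefView(source)
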