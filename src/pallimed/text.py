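"""Tokenization shared by the lexicon and the extraction pipeline.

Clinical notes mix cases, punctuation and units freely ("Fentanyl
25mcg/hr patch; morphine PRN."). The tokenizer lower-cases (Unicode
case folding) and splits on whitespace and punctuation, but keeps
hyphens *inside* tokens so compound drug names such as
"piperacillin-tazobactam" survive as a single token. No stemming is
applied: plural or inflected drug names are handled only through
explicit lexicon surface forms.
"""

from __future__ import annotations

import re

# word characters (minus underscore), optionally hyphen-joined
_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Split free text into lower-cased tokens.

    Parameters
    ----------
    text : str
        Raw note text; may be empty.

    Returns
    -------
    list of str
        Tokens in reading order. Hyphens are preserved within tokens;
        all other punctuation acts as a separator.

    Examples
    --------
    >>> tokenize("Fentanyl 25mcg/hr patch; morphine PRN.")
    ['fentanyl', '25mcg', 'hr', 'patch', 'morphine', 'prn']
    >>> tokenize("piperacillin-tazobactam given")
    ['piperacillin-tazobactam', 'given']
    """
    if not text:
        return []
    return _TOKEN_RE.findall(text.casefold())
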