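{
  "name": "monk",
  "source": "Monk Skin Tone Scale reference swatches, skintone.google (tone 1 lightest to tone 10 darkest)",
  "swatches": [
    {"label": 1, "hex": "#f6ede4"},
    {"label": 2, "hex": "#f3e7db"},
    {"label": 3, "hex": "#f7ead0"},
    {"label": 4, "hex": "#eadaba"},
    {"label": 5, "hex": "#d7bd96"},
    {"label": 6, "hex": "#a07e56"},
    {"label": 7, "hex": "#825c43"},
    {"label": 8, "hex": "#604134"},
    {"label": 9, "hex": "#3a312a"},
    {"label": 10, "hex": "#292420"}
  ]
}
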