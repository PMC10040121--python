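>LsAMP-1 Laurentiella sp. defensin precursor, scaffold LASS02013305.1 [977 - 771]
MVFSKSFLLTLYFFIATILLNLVQADVDVGSCFVFLPDYRSDCNGYCQQRGYKGGHCGSIFNVKCWCET
>LsAMP-2 Laurentiella sp. defensin precursor, scaffold LASS02014383.1 [1468 - 1070]
MSINSQIRVLVLFVFLVLTYINQVSADVLIGSCVWGAVDYKSDCSGYCESRGYSGGHCGSFGNVDCWCNVDE
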