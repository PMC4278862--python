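>synthetic_GH5-5_ref_1 synthetic reference panel member (no real GH5-5 sequence available offline)
NFDHEYLSMWQCWRRHADMELDGHLMWYGSPRDWGGWPLKNLDVTHWSPEIEDCIVKHDC
CMQLYAHQWW
>synthetic_GH5-5_ref_2 synthetic reference panel member (no real GH5-5 sequence available offline)
NFDHDYLQMWQAWMRHEDQEMDVHNMWHYSPRDERQHLLKNGDEMHWSPEIEDCKVLHLC
CQQLLAHGWW
>synthetic_GH5-5_ref_3 synthetic reference panel member (no real GH5-5 sequence available offline)
NFCHDYLQMWSCVRRHEDMEMDGHLMWHNCPLDELGWMLCAGDEPHWSPCGEVCKVKHPC
CQQLLAHGYW
>synthetic_GH5-5_ref_4 synthetic reference panel member (no real GH5-5 sequence available offline)
NFDTDPCQASFCWMRHEDPRMDGHLMWRYSPRFEGQWHLKNSDETIWSPEIEGCKVKYPC
CRQLLAHGWW
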