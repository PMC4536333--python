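(mm_oanatinus5, ((mm_cfamiliaris3, (mm_btaurus, (mm_ttruncatus, (mm_balaenoptera, mm_bmysticetus)))), (mm_hsapiens10, mm_mmusculus5)));
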