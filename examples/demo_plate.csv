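well_id,subject_id,group_label,genotype,treatment,dose,dose_unit,plate_id
A01,larva001,scrambled,scrambled,none,0.0,,demo1
A02,larva002,scrambled,scrambled,none,0.0,,demo1
A03,larva003,scrambled,scrambled,none,0.0,,demo1
A04,larva004,scrambled,scrambled,none,0.0,,demo1
A05,larva005,scrambled,scrambled,none,0.0,,demo1
A06,larva006,scrambled,scrambled,none,0.0,,demo1
A07,larva007,scrambled,scrambled,none,0.0,,demo1
A08,larva008,scrambled,scrambled,none,0.0,,demo1
A09,larva009,scrambled,scrambled,none,0.0,,demo1
A10,larva010,scrambled,scrambled,none,0.0,,demo1
A11,larva011,scrambled,scrambled,none,0.0,,demo1
A12,larva012,scrambled,scrambled,none,0.0,,demo1
A13,larva013,scrambled,scrambled,none,0.0,,demo1
A14,larva014,scrambled,scrambled,none,0.0,,demo1
A15,larva015,scrambled,scrambled,none,0.0,,demo1
A16,larva016,scrambled,scrambled,none,0.0,,demo1
A17,larva017,scrambled,scrambled,none,0.0,,demo1
A18,larva018,scrambled,scrambled,none,0.0,,demo1
A19,larva019,scn1lab,scn1lab,none,0.0,,demo1
A20,larva020,scn1lab,scn1lab,none,0.0,,demo1
A21,larva021,scn1lab,scn1lab,none,0.0,,demo1
A22,larva022,scn1lab,scn1lab,none,0.0,,demo1
A23,larva023,scn1lab,scn1lab,none,0.0,,demo1
A24,larva024,scn1lab,scn1lab,none,0.0,,demo1
A25,larva025,gabra1,gabra1,none,0.0,,demo1
A26,larva026,gabra1,gabra1,none,0.0,,demo1
A27,larva027,gabra1,gabra1,none,0.0,,demo1
A28,larva028,gabra1,gabra1,none,0.0,,demo1
A29,larva029,gabra1,gabra1,none,0.0,,demo1
A30,larva030,gabra1,gabra1,none,0.0,,demo1
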