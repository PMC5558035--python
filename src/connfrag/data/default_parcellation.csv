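region_id,name,hemisphere,language_specific,domain_general,roi_tag
L001,left region 1,L,0,0,none
L002,left region 2,L,0,0,none
L003,left region 3,L,0,0,none
L004,left region 4,L,0,0,none
L005,left region 5,L,0,0,none
L006,posterior superior frontal gyrus,L,0,1,SFG_post
L007,middle frontal gyrus dorsal prefrontal cortex,L,0,1,MFG_DPFC
L008,left region 8,L,0,0,none
L009,left region 9,L,0,0,none
L010,left region 10,L,0,0,none
L011,posterior middle frontal gyrus,L,1,0,MFG_post
L012,inferior frontal gyrus pars opercularis,L,1,0,pars_opercularis
L013,inferior frontal gyrus pars triangularis,L,1,0,pars_triangularis
L014,inferior frontal gyrus pars orbitalis,L,0,1,IFG_orbitalis
L015,left region 15,L,0,0,none
L016,precentral gyrus,L,0,1,PrCG
L017,left region 17,L,0,0,none
L018,left region 18,L,0,0,none
L019,left region 19,L,0,0,none
L020,left region 20,L,0,0,none
L021,superior temporal gyrus,L,1,0,STG
L022,superior temporal gyrus pole,L,1,0,STG_pole
L023,middle temporal gyrus,L,1,0,MTG
L024,posterior middle temporal gyrus,L,1,0,PMTG
L025,posterior inferior temporal gyrus,L,1,0,PITG
L026,left region 26,L,0,0,none
L027,left region 27,L,0,0,none
L028,left region 28,L,0,0,none
L029,left region 29,L,0,0,none
L030,left region 30,L,0,0,none
L031,angular gyrus,L,1,0,AG
L032,superior parietal gyrus,L,0,1,SPG
L033,supramarginal gyrus,L,0,1,SMG
L034,left region 34,L,0,0,none
L035,left region 35,L,0,0,none
L036,left region 36,L,0,0,none
L037,left region 37,L,0,0,none
L038,left region 38,L,0,0,none
L039,left region 39,L,0,0,none
L040,left region 40,L,0,0,none
L041,posterior cingulate cortex,L,0,1,PCC
L042,left region 42,L,0,0,none
L043,left region 43,L,0,0,none
L044,left region 44,L,0,0,none
L045,left region 45,L,0,0,none
L046,insula,L,0,1,insula
L047,left region 47,L,0,0,none
L048,left region 48,L,0,0,none
L049,left region 49,L,0,0,none
L050,left region 50,L,0,0,none
L051,left region 51,L,0,0,none
L052,left region 52,L,0,0,none
L053,left region 53,L,0,0,none
L054,left region 54,L,0,0,none
L055,left region 55,L,0,0,none
L056,left region 56,L,0,0,none
L057,left region 57,L,0,0,none
R001,right region 1,R,0,0,none
R002,right region 2,R,0,0,none
R003,right region 3,R,0,0,none
R004,right region 4,R,0,0,none
R005,right region 5,R,0,0,none
R006,right region 6,R,0,0,none
R007,right region 7,R,0,0,none
R008,right region 8,R,0,0,none
R009,right region 9,R,0,0,none
R010,right region 10,R,0,0,none
R011,right region 11,R,0,0,none
R012,right region 12,R,0,0,none
R013,right region 13,R,0,0,none
R014,right region 14,R,0,0,none
R015,right region 15,R,0,0,none
R016,right region 16,R,0,0,none
R017,right region 17,R,0,0,none
R018,right region 18,R,0,0,none
R019,right region 19,R,0,0,none
R020,right region 20,R,0,0,none
R021,right region 21,R,0,0,none
R022,right region 22,R,0,0,none
R023,right region 23,R,0,0,none
R024,right region 24,R,0,0,none
R025,right region 25,R,0,0,none
R026,right region 26,R,0,0,none
R027,right region 27,R,0,0,none
R028,right region 28,R,0,0,none
R029,right region 29,R,0,0,none
R030,right region 30,R,0,0,none
R031,right region 31,R,0,0,none
R032,right region 32,R,0,0,none
R033,right region 33,R,0,0,none
R034,right region 34,R,0,0,none
R035,right region 35,R,0,0,none
R036,right region 36,R,0,0,none
R037,right region 37,R,0,0,none
R038,right region 38,R,0,0,none
R039,right region 39,R,0,0,none
R040,right region 40,R,0,0,none
R041,right region 41,R,0,0,none
R042,right region 42,R,0,0,none
R043,right region 43,R,0,0,none
R044,right region 44,R,0,0,none
R045,right region 45,R,0,0,none
R046,right region 46,R,0,0,none
R047,right region 47,R,0,0,none
R048,right region 48,R,0,0,none
R049,right region 49,R,0,0,none
R050,right region 50,R,0,0,none
R051,right region 51,R,0,0,none
R052,right region 52,R,0,0,none
R053,right region 53,R,0,0,none
R054,right region 54,R,0,0,none
R055,right region 55,R,0,0,none
R056,right region 56,R,0,0,none
R057,right region 57,R,0,0,none
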