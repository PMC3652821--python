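1100001G20Rik
Acp2
Atp6ap2
B4galnt1
Bcl2a1a
Bcl2a1b
Bcl2a1d
Bst1
C1qb
C1ra
C1rb
C2
C3
Capg
Ccl6
Ccl9
Cd14
Cd1d1
Cd200r1
Cd68
Cfb
Ch25h
Chi3l1
Chi3l3
Clec4a2
Clec4n
Clec7a
Clu
Cp
Csf2rb2
Ctsb
Ctsk
Ctss
Ctsz
Cxcl17
Cxcl2
Cyba
Cybb
Dab2
Dbp
Emr1
F10
Fn1
Fpr2
Gatm
Grn
H2-Ab1
Havcr2
Hvcn1
Id2
Ifi30
Ifit3
Igf1
Il1rn
Il33
Itgax
Itgb2
Itih4
Lair1
Laptm5
Lbp
Lgals3bp
Lrg1
Ly6i
Matn4
Mmp12
Ms4a6d
Ms4a7
Mtm1
Muc1
Naip1-rs1
Naip2
Olfm1
Olr1
Orm1
Orm2
Per3
Pigr
Pon1
Prkcd
Procr
Psap
Ptgs1
Rab20
Rab32
Reg3g
Rmcs2
Saa3
Sirpa
Slc26a4
Slc3a2
Slc6a20a
Smpdl3b
Snx10
Tgfbi
Tgfbr1
Tifa
Tlr7
Tmem106a
U46068
Vnn1
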