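student_id,prokaryotes_protists_funguses,plants,invertebrates,fishes,amphibians,reptiles,birds,wild_mammals,domestic_mammals,human
S_1,0,0,0,0,0,3,8,4.67,9.5,5
S_2,0,3.5,0,0,0,0,0,3.5,9,7
S_3,0,0,0,0,0,6.33,9,7,4,0
S_4,0,0,2.5,9,0,0,3,5.6,0,10
S_5,0,0,0,0,0,0,0,0,0,5.5
S_6,6,5,3,0,0,0,0,1.5,8.5,4
S_7,0,0,3,0,0,0,0,5.25,6.2,0
S_8,9.5,0,0,0,0,0,2,3.75,5,8
S_9,0,0,0,0,0,5.33,8,1.5,7,0
S_10,0,0,0,0,0,4.5,0,8,2.5,0
S_11,0,0,0,0,0,0,1,2,0,6.5
S_12,0,2,3,10,0,4,9,1,6.67,6
S_13,0,0,0,1,0,0,0,4.5,7.2,0
S_14,0,0,0,9,4,3,10,4.33,7.5,0
S_15,0,0,8,9,0,0,6,3,7,10
S_16,0,5,8,9,0,2,7,0,0,10
S_17,0,4.33,6,5,0,0,0,0,0,7
S_18,0,0,5.33,0,0,4,0,8.5,4.5,0
S_19,0,6,5,0,0,0,0,3.75,7.5,7
S_20,3.5,0,5.5,0,0,0,8,4.5,0,10
S_21,0,0,0,0,0,0,3,5.6,7.67,1
S_22,0,4,0,0,0,2,0,4.75,6.67,10
S_23,0,0,1.5,0,0,0,4,7,6.33,8
S_24,1,10,9,0,0,0,2,7.5,5,3
S_25,0,8,0,5,0,0,2.5,6,2.5,10
S_26,7,1.5,10,3,0,8,4,6,0,0
S_27,0,0,0,0,0,3,0,4.67,6.25,10
S_28,7,0,0,0,3,4,8,2,1,0
S_29,5.5,3,0,0,0,10,9,8,0,0
S_30,0,4,0,3,0,0,0,7,8,1.5
S_31,6,7,3,0,0,0,0,7,0,10
S_32,0,0,7,0,0,0,9.5,8,0,4
S_33,6,4.5,1,0,0,9.5,0,3,4.5,8
S_34,0,5.5,0,0,0,0,7,0,5.29,0
S_35,0,5.5,0,7,0,0,8,3,6.5,10
S_36,0,0,0,0,0,0,0,0,5,5.56
S_37,0,6,8,0,0,3,4,2,6.67,0
S_38,0,1.5,0,0,0,5,0,6.33,7.67,0
S_39,0,7,0,0,0,0,10,4,2.5,0
S_40,1.5,0,0,0,0,5.5,0,9,4.67,9
S_41,6.25,9,0,0,0,0,0,7,0,8
S_42,7,5.5,3,0,0,9,5,0,0,0
S_43,0,10,1,0,0,2,7.5,6,6,3
S_44,0,0,9,0,0,3,10,4.5,5.5,2
S_45,0,0,5.5,0,0,2.5,7,8,6,2
S_46,0,0,0,0,4,3,7,9,4.4,10
S_47,0,3.67,0,0,0,0,6,4.33,9.5,0
S_48,0,8,0,0,0,6,3,4.83,0,9
S_49,6,9,0,0,0,0,4,2.5,4.5,10
S_50,0,4.67,0,0,0,0,0,4.75,7,8
S_51,0,6.5,0,0,0,0,4,7.33,4,0
S_52,0,2,0,0,5,0,0,5.67,8.5,10
S_53,0,0,4.6,0,7,0,1,0,5,9
S_54,0,0,2.5,2,0,7.5,3,8.33,5,0
S_55,0,5.33,4.33,0,0,0,6,0,5.5,9
S_56,0,9,0,0,0,0,2.33,3,6,9
S_57,0,9,0,0,0,1,4,4.33,6,10
S_58,0,0,0,7,4,6,10,2.5,7.33,1
S_59,0,0,6,2,7,1,8,4,9.5,0
S_60,0,0,5.5,4,0,1,8,2.5,9.5,7
S_61,0,0,1,0,0,5.5,0,6.33,4.67,10
S_62,0,5,10,2,0,4,3,0,7.67,4
S_63,0,0,2.5,6,0,0,8,3.33,8.67,0
S_64,10,7,2,0,8,0,0,5,9,0
S_65,1.5,5.75,4,0,0,0,0,0,9,7
S_66,0,2,0,0,0,0,4,7,8,7
S_67,0,4,4,0,2,6.5,6,0,10,0
S_68,0,5.5,0,1,0,4,0,5.5,7,10
S_69,0,4,0,4,0,3,7,0,9,5.5
S_70,0,7,0,9,0,4.5,3.5,0,7,2
S_71,0,0,0,10,0,6.5,1.5,5,9,0
S_72,0,0,0,8,0,2,6,6.5,2,9
S_73,0,0,2,0,0,8,3,7.4,2.5,0
S_74,0,7,1.5,0,0,0,6,4,8.5,10
S_75,0,4.25,0,0,0,3,6,0,8.33,4
S_76,0,0,0,5,0,2,6,5.4,7.5,0
S_77,0,0,2.5,9,1,0,0,7.5,6.25,0
S_78,1,0,0,10,9,6,5,5.67,3.5,0
S_79,0,1.5,3.5,5,0,0,7,0,7.67,10
S_80,1,2,0,0,3,0,0,4.5,7.5,10
S_81,4.5,1,2,0,0,6,6,9.5,0,0
S_82,0,7,2,0,0,8,1,4.5,6,10
S_83,0,8,0,0,0,0,0,5.5,4.67,5.67
S_84,0,7,9,0,0,3.5,0,1.5,7.25,0
S_85,0,0,0,0,0,0,3,7.33,1.5,5
S_86,8.34,3,1,0,0,0,0,5,7.5,0
S_87,9,0,8,2,0,0,0,5,1,10
S_88,6,4,0,1,0,0,6,5,9,0
S_89,7,5.33,6,0,2,0,3,5,10,0
S_90,6,0,3.33,0,0,3,5,7,8.5,0
S_91,0,7,10,8,0,2,9,3.33,5,4
S_92,0,9,6.67,7,0,1,6.5,3,0,2
S_93,5.6,0,3,0,0,0,6,4.5,9,0
S_94,7,0,8,0,0,1,6,6.25,0,3
S_95,6,9,1,0,0,10,7,2.5,8,5
S_96,5.25,8,4,0,5,3,0,6,0,0
S_97,6,0,0,6,0,0,0,1.5,10,3
S_98,0,2,6.5,0,0,5,2,6,9,10
S_99,5.5,8,0,6,0,5,0,1.5,9.5,3
S_100,0,1.5,3,4,0,0,6.5,6.5,9,10
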