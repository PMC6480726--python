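# Default 27-bucket table, 1.03-8.52 ppm, 60 MHz urine profiles.
# Named metabolite buckets are anchored assignments; "filler_*" windows tile
# the remaining unexcluded span and are flagged unanchored.
low,high,label,anchored
1.03,1.14,filler_1.03-1.14,False
1.14,1.25,3_hydroxybutyrate,True
1.25,1.34,lactate,True
1.34,1.44,filler_1.34-1.44,False
1.44,1.52,alanine,True
1.52,1.61,filler_1.52-1.61,False
1.87,1.99,acetate,True
1.99,2.13,n_acetyl,True
2.14,2.29,acetone,True
2.29,2.42,filler_2.29-2.42,False
2.53,2.70,citrate,True
2.98,3.14,creatinine,True
3.14,3.99,glucose_bulk,True
3.99,4.20,filler_3.99-4.20,False
4.20,4.41,filler_4.20-4.41,False
5.17,5.36,glucose_c1h,True
5.56,5.71,filler_5.56-5.71,False
5.71,5.86,filler_5.71-5.86,False
6.83,6.96,filler_6.83-6.96,False
6.96,7.09,filler_6.96-7.09,False
7.15,7.33,indoxyl_sulfate,True
7.33,7.55,filler_7.33-7.55,False
7.55,7.71,hippurate,True
7.71,7.86,filler_7.71-7.86,False
7.86,8.02,filler_7.86-8.02,False
8.14,8.33,filler_8.14-8.33,False
8.33,8.52,formate,True
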